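"""Threshold configuration and analysis-mode flags.

Every numeric cutoff used by any detector lives in :class:`ThresholdConfig`
and can be overridden by the user through the config file or ``--set``
CLI options. Distances are Å, angles degrees. All distance/angle thresholds
are inclusive (``<=`` / ``>=``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["ThresholdConfig", "AnalysisMode", "ConfigError", "load_config",
           "parse_overrides", "DEFAULT_LIGAND_EXCLUSIONS"]

#: ubiquitous buffer/cryoprotectant molecules excluded from ligand candidacy
#: by default (restorable via configuration)
DEFAULT_LIGAND_EXCLUSIONS = (
    "GOL", "EDO", "SO4", "PO4", "ACT", "DMS", "PEG", "PG4", "MPD", "BME",
    "TRS", "EPE", "MES", "FMT", "NO3",
)


class ConfigError(ValueError):
    """Invalid configuration key or value."""


@dataclass
class ThresholdConfig:
    """Geometric cutoffs for the eight interaction detectors.

    Defaults follow the published defaults of the reference interaction
    profiling engine so results on real complexes are comparable.
    """

    #: max C-C distance for a hydrophobic contact
    hydroph_dist_max: float = 4.0
    #: max donor-acceptor heavy-atom distance for a hydrogen bond
    hbond_dist_max: float = 4.1
    #: min D-H...A angle for a hydrogen bond
    hbond_don_angle_min: float = 100.0
    #: max ring-centroid distance for pi-stacking
    pistack_dist_max: float = 5.5
    #: allowed deviation from 0 deg (parallel) or 90 deg (T-shape)
    pistack_ang_dev: float = 30.0
    #: max lateral centroid offset for pi-stacking
    pistack_offset_max: float = 2.0
    #: max ring-centroid to charge-centroid distance for pi-cation
    pication_dist_max: float = 6.0
    #: max face-on deviation (ring normal vs centroid->cation) for
    #: guanidinium cations
    pication_face_angle_max: float = 30.0
    #: max centroid-centroid distance between opposite charges
    saltbridge_dist_max: float = 5.5
    #: max X...acceptor distance for a halogen bond
    halogen_dist_max: float = 4.0
    #: ideal C-X...A donor angle and tolerance
    halogen_don_angle: float = 165.0
    halogen_don_angle_dev: float = 30.0
    #: ideal Y-A...X acceptor angle and tolerance
    halogen_acc_angle: float = 120.0
    halogen_acc_angle_dev: float = 30.0
    #: distance window for each leg of a water bridge
    water_bridge_mindist: float = 2.5
    water_bridge_maxdist: float = 4.1
    #: window for the polar-Owat-polar angle at the bridging water
    water_bridge_omega_min: float = 75.0
    water_bridge_omega_max: float = 140.0
    #: max metal-target coordination distance
    metal_dist_max: float = 3.0
    #: binding-site shell: receptor residues with any heavy atom within this
    #: distance of any ligand heavy atom
    binding_site_dist: float = 7.5
    #: max RMSD from the best-fit plane for an aromatic ring
    ring_planarity_max: float = 0.25
    #: treat fluorine as a halogen-bond donor (weak sigma-hole; off by default)
    fluorine_as_donor: bool = False

    _PAIRED_BOUNDS = (
        ("water_bridge_mindist", "water_bridge_maxdist"),
        ("water_bridge_omega_min", "water_bridge_omega_max"),
    )

    def validate(self) -> "ThresholdConfig":
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            value = getattr(self, f.name)
            if isinstance(value, bool):
                continue
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigError(f"{f.name} must be a positive number, got {value!r}")
        for lo, hi in self._PAIRED_BOUNDS:
            if getattr(self, lo) >= getattr(self, hi):
                raise ConfigError(f"{lo} must be < {hi}")
        return self

    @classmethod
    def field_names(cls) -> list:
        return [f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")]

    def replace(self, **overrides) -> "ThresholdConfig":
        unknown = set(overrides) - set(self.field_names())
        if unknown:
            raise ConfigError(
                f"unknown threshold key(s) {sorted(unknown)}; "
                f"valid keys: {', '.join(self.field_names())}")
        return dataclasses.replace(self, **overrides).validate()

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.field_names()}


@dataclass
class AnalysisMode:
    """Mode flags controlling receptor/ligand assignment and scope."""

    #: when True, U/A/C/G and DT/DA/DC/DG residues belong to the receptor;
    #: when False (default) each contiguous nucleic chain becomes one
    #: ligand entity
    nucleic_acids_as_receptor: bool = False
    #: report contacts between a chain ligand and its own chain
    intra_chain: bool = True
    #: treat modified residues covalently linked into a polymer as ligands
    modified_residues_as_ligand: bool = False
    #: hetero residue names never considered ligands
    ligand_exclusion_list: tuple = DEFAULT_LIGAND_EXCLUSIONS
    #: treat lone metal ions as ligand entities
    ions_as_ligands: bool = True

    _FLAG_NAMES = ("nucleic_acids_as_receptor", "intra_chain",
                   "modified_residues_as_ligand", "ions_as_ligands")

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self._FLAG_NAMES}
        d["ligand_exclusion_list"] = ",".join(self.ligand_exclusion_list)
        return d


_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


def _coerce(key: str, raw: str, current):
    raw = raw.strip()
    if isinstance(current, bool):
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ConfigError(f"{key}: expected a boolean, got {raw!r}")
    if isinstance(current, tuple):
        return tuple(x.strip().upper() for x in raw.split(",") if x.strip())
    try:
        return float(raw)
    except ValueError as exc:
        raise ConfigError(f"{key}: expected a number, got {raw!r}") from exc


def parse_overrides(pairs: Iterable[str],
                    config: ThresholdConfig,
                    mode: AnalysisMode):
    """Apply ``KEY=VALUE`` override strings to a config + mode pair."""
    cfg_updates = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigError(f"override {pair!r} is not KEY=VALUE")
        key, _, raw = pair.partition("=")
        key = key.strip()
        if key in ThresholdConfig.field_names():
            cfg_updates[key] = _coerce(key, raw, getattr(config, key))
        elif key in AnalysisMode._FLAG_NAMES or key == "ligand_exclusion_list":
            setattr(mode, key, _coerce(key, raw, getattr(mode, key)))
        else:
            valid = ThresholdConfig.field_names() + list(AnalysisMode._FLAG_NAMES) \
                + ["ligand_exclusion_list"]
            raise ConfigError(
                f"unknown configuration key {key!r}; valid keys: {', '.join(valid)}")
    config = config.replace(**cfg_updates) if cfg_updates else config.validate()
    return config, mode


def load_config(path) -> tuple:
    """Load a flat ``key = value`` config file.

    Blank lines and ``#`` comments are ignored; unknown keys are rejected;
    values are unit-checked (positive, min < max). Returns
    ``(ThresholdConfig, AnalysisMode)``.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            pairs.append(line)
    return parse_overrides(pairs, ThresholdConfig(), AnalysisMode())
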