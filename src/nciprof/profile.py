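"""End-to-end profiling pipeline.

Four stages: structure preparation (parsing, model selection,
hydrogenation), receptor/ligand splitting with binding-site extraction,
functional characterisation of both sides, and rule-based interaction
detection with refinement. :func:`profile_structure` runs them all and
returns a :class:`ProfileResult` the reporting layer serialises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .bonds import perceive_bonds
from .config import AnalysisMode, ThresholdConfig
from .detect import audit_interactions, detect_all
from .features import (FeatureSet, WaterOxygen, perceive_ligand_features,
                       perceive_residue_features)
from .hydrogens import HydrogenationReport, ensure_hydrogens
from .prepare import (BindingSite, LigandEntity, build_binding_site,
                      classify_receptor_scope, extract_ligands)
from .structure import Structure, parse_pdb, select_model

__all__ = ["SiteResult", "ProfileResult", "profile_structure", "profile_site"]


@dataclass
class SiteResult:
    """Interactions of one binding site, plus the features that produced them."""

    site: BindingSite
    interactions: dict                 # itype -> list of records
    lig_features: FeatureSet
    rec_features: FeatureSet

    @property
    def ligand(self) -> LigandEntity:
        return self.site.ligand

    def count(self, itype: str) -> int:
        return len(self.interactions.get(itype, []))

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.interactions.values())


@dataclass
class ProfileResult:
    input_name: str
    structure: Structure
    config: ThresholdConfig
    mode: AnalysisMode
    hydrogenation: HydrogenationReport
    sites: list = field(default_factory=list)


def profile_site(structure: Structure, ligand: LigandEntity,
                 cfg: ThresholdConfig, mode: AnalysisMode,
                 adjacency) -> SiteResult:
    """Characterise and profile a single ligand entity's binding site."""
    site = build_binding_site(structure, ligand, cfg)
    site = classify_receptor_scope(site, mode)
    lig_features = perceive_ligand_features(ligand, adjacency, cfg)
    rec_features = FeatureSet()
    for res in site.receptor_residues:
        rec_features.extend(perceive_residue_features(res, adjacency, cfg))
    waters = []
    for wres in site.waters:
        o = next((a for a in wres.atoms if a.element == "O"), None)
        if o is not None:
            waters.append(WaterOxygen(o))
    interactions = detect_all(lig_features, rec_features, waters, cfg,
                              adjacency=adjacency)
    violations = audit_interactions(interactions, cfg)
    if violations:  # pragma: no cover - internal consistency guard
        raise AssertionError(
            "reported geometry violates active thresholds: " + "; ".join(violations))
    return SiteResult(site, interactions, lig_features, rec_features)


def profile_structure(source: Union[str, Structure],
                      config: Optional[ThresholdConfig] = None,
                      mode: Optional[AnalysisMode] = None,
                      model: int = 1,
                      input_name: Optional[str] = None) -> ProfileResult:
    """Profile all ligand binding sites of one structure.

    ``source`` may be PDB text, a path to a ``.pdb`` file, or an already
    parsed :class:`Structure`. ``model`` selects the coordinate model of
    multi-model (e.g. NMR) inputs, 1-based.
    """
    cfg = (config or ThresholdConfig()).validate()
    mode = mode or AnalysisMode()
    if isinstance(source, Structure):
        structure = source
    else:
        structure = parse_pdb(source)
        if input_name is None and isinstance(source, str) and "\n" not in source:
            input_name = source
    select_model(structure, model)
    h_report = ensure_hydrogens(structure)
    adjacency = perceive_bonds(list(structure.atoms()), structure.conect)
    ligands = extract_ligands(structure, mode)
    result = ProfileResult(
        input_name=input_name or structure.header_id or "structure",
        structure=structure, config=cfg, mode=mode, hydrogenation=h_report)
    for ligand in ligands:
        result.sites.append(profile_site(structure, ligand, cfg, mode, adjacency))
    return result
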