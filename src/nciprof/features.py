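"""Functional characterisation: perceive the chemical features the geometric
interaction rules consume.

Three perception routes exist. Standard amino acids and nucleotides are
assigned donors/acceptors, charged centres and aromatic rings from
residue-name templates (assuming pH 7 protonation states). Arbitrary hetero
ligands are perceived generically from the bond graph: donors/acceptors by
element and valence, rings by cycle perception plus a planarity and
bond-length test, charges by functional-group rules (carboxylate, phosphate,
sulfate, guanidinium/amidinium, protonated or quaternary amines). Hydrophobic
atoms follow one definitional rule everywhere: a carbon whose bonded heavy
neighbours are all carbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import networkx as nx
import numpy as np

from .bonds import heavy_neighbors
from .config import ThresholdConfig
from .geometry import centroid, fit_plane
from .structure import METAL_SYMBOLS, Atom, Residue
from .templates import get_template

logger = logging.getLogger(__name__)

__all__ = [
    "HBondDonor", "HBondAcceptor", "ChargedCenter", "AromaticRing",
    "HydrophobicAtom", "HalogenDonor", "MetalAtom", "WaterOxygen",
    "FeatureSet", "perceive_residue_features", "perceive_ligand_features",
    "ligand_polar_roles",
]

HALOGENS = {"F", "CL", "BR", "I"}

#: phosphate/sugar atom-name aliases (older PDB convention)
_ALIASES = {"O1P": "OP1", "O2P": "OP2", "O2*": "O2'", "O4*": "O4'",
            "O5*": "O5'", "O3*": "O3'"}


def _canon(name: str) -> str:
    return _ALIASES.get(name, name)


@dataclass
class HBondDonor:
    donor_atom: Atom
    hydrogens: list = dc_field(default_factory=list)
    #: True when hydrogen placement failed; the donor is then evaluated
    #: distance-only and resulting bonds are flagged lower-confidence
    missing_h: bool = False


@dataclass
class HBondAcceptor:
    acceptor_atom: Atom


@dataclass
class ChargedCenter:
    atoms: list
    sign: str                      # "positive" | "negative"
    label: str = ""                # functional-group name
    centroid: np.ndarray = None

    def __post_init__(self):
        if self.centroid is None:
            self.centroid = centroid([a.coords for a in self.atoms])

    @property
    def residue(self) -> Residue:
        return self.atoms[0].parent

    @property
    def is_guanidinium(self) -> bool:
        return self.label in ("guanidinium", "amidinium")


@dataclass
class AromaticRing:
    atoms: list                    # ring atoms, cyclic order (composite: any order)
    centroid: np.ndarray = None
    normal: np.ndarray = None
    planarity_rmsd: float = 0.0
    #: rings of one fused system share a key so stacking keeps one record
    system_key: tuple = None
    label: str = ""                # e.g. "ring6", "ring5", "fused"

    def __post_init__(self):
        if self.centroid is None:
            self.centroid, self.normal, self.planarity_rmsd = fit_plane(
                [a.coords for a in self.atoms])
        if self.system_key is None:
            self.system_key = (self.atoms[0].parent.key,
                               tuple(sorted(a.serial for a in self.atoms)))

    @property
    def residue(self) -> Residue:
        return self.atoms[0].parent


@dataclass
class HydrophobicAtom:
    atom: Atom


@dataclass
class HalogenDonor:
    halogen: Atom
    carbon: Atom


@dataclass
class MetalAtom:
    atom: Atom


@dataclass
class WaterOxygen:
    atom: Atom


@dataclass
class FeatureSet:
    """All perceived features of one side (receptor or ligand) of a site."""

    donors: list = dc_field(default_factory=list)
    acceptors: list = dc_field(default_factory=list)
    pos_charges: list = dc_field(default_factory=list)
    neg_charges: list = dc_field(default_factory=list)
    rings: list = dc_field(default_factory=list)
    hydrophobics: list = dc_field(default_factory=list)
    halogen_donors: list = dc_field(default_factory=list)
    metals: list = dc_field(default_factory=list)
    waters: list = dc_field(default_factory=list)

    def extend(self, other: "FeatureSet") -> "FeatureSet":
        for name in ("donors", "acceptors", "pos_charges", "neg_charges",
                     "rings", "hydrophobics", "halogen_donors", "metals",
                     "waters"):
            getattr(self, name).extend(getattr(other, name))
        return self


def _attached_hydrogens(atom: Atom, adjacency) -> list:
    return [n for n in adjacency.get(atom, ()) if n.element == "H"]


def _add_hydrophobics(fs: FeatureSet, atoms, adjacency):
    for a in atoms:
        if a.element != "C":
            continue
        if all(n.element == "C" for n in heavy_neighbors(a, adjacency)):
            fs.hydrophobics.append(HydrophobicAtom(a))


def _ring_from_names(res: Residue, names: list) -> Optional[list]:
    atoms = [res.get_atom(n) for n in names]
    if any(a is None for a in atoms):
        return None
    return atoms


def perceive_residue_features(res: Residue, adjacency,
                              cfg: Optional[ThresholdConfig] = None) -> FeatureSet:
    """Features of one receptor residue (amino acid, nucleotide or water).

    Residues without a template (modified residues kept in the receptor)
    fall back to generic graph perception with a logged warning.
    """
    cfg = cfg or ThresholdConfig()
    fs = FeatureSet()
    if res.kind == "water":
        o = next((a for a in res.atoms if a.element == "O"), None)
        if o is not None:
            fs.waters.append(WaterOxygen(o))
        return fs
    if res.kind == "metal_ion":
        fs.metals.append(MetalAtom(res.atoms[0]))
        return fs
    if res.kind == "amino_acid":
        return _perceive_amino_acid(res, adjacency, cfg, fs)
    if res.is_nucleic:
        return _perceive_nucleotide(res, adjacency, cfg, fs)
    logger.warning("no template for receptor residue %s; generic perception",
                   res.label)
    return _perceive_generic(res.atoms, adjacency, cfg, fs)


def _make_donor(atom: Atom, adjacency) -> HBondDonor:
    hs = _attached_hydrogens(atom, adjacency)
    return HBondDonor(atom, hs, missing_h=not hs)


def _perceive_amino_acid(res, adjacency, cfg, fs):
    tpl = get_template(res.name)
    # backbone: amide N donor (except proline), carbonyl O (+ OXT) acceptors
    n = res.get_atom("N")
    if n is not None and res.name != "PRO":
        fs.donors.append(_make_donor(n, adjacency))
    for name in ("O", "OXT"):
        o = res.get_atom(name)
        if o is not None:
            fs.acceptors.append(HBondAcceptor(o))
    if tpl is not None:
        for name in tpl.donors:
            a = res.get_atom(name)
            if a is not None:
                fs.donors.append(_make_donor(a, adjacency))
        for name in tpl.acceptors:
            a = res.get_atom(name)
            if a is not None:
                fs.acceptors.append(HBondAcceptor(a))
        for names, label in tpl.neg_charges:
            atoms = [res.get_atom(x) for x in names]
            if all(a is not None for a in atoms):
                fs.neg_charges.append(ChargedCenter(atoms, "negative", label))
        for names, label in tpl.pos_charges:
            atoms = [res.get_atom(x) for x in names]
            if all(a is not None for a in atoms):
                fs.pos_charges.append(ChargedCenter(atoms, "positive", label))
        for names, label in tpl.pos_charges_conditional:
            # His-type: cationic only when both ring nitrogens carry hydrogens
            atoms = [res.get_atom(x) for x in names]
            if all(a is not None for a in atoms):
                ring_n = [a for a in atoms if a.element == "N"]
                if ring_n and all(_attached_hydrogens(a, adjacency) for a in ring_n):
                    fs.pos_charges.append(ChargedCenter(atoms, "positive", label))
        for names in tpl.rings:
            atoms = _ring_from_names(res, names)
            if atoms is not None:
                fs.rings.append(AromaticRing(atoms, label=f"ring{len(atoms)}"))
    _add_hydrophobics(fs, res.atoms, adjacency)
    return fs


def _perceive_nucleotide(res, adjacency, cfg, fs):
    by_canon = {_canon(a.name): a for a in res.atoms}
    # phosphate: the two free phosphate oxygens form one negative centre
    free_p_oxy = [by_canon[n] for n in ("OP1", "OP2") if n in by_canon]
    if len(free_p_oxy) == 2:
        fs.neg_charges.append(ChargedCenter(free_p_oxy, "negative", "phosphate"))
    for a in free_p_oxy:
        fs.acceptors.append(HBondAcceptor(a))
    if "O4'" in by_canon:
        fs.acceptors.append(HBondAcceptor(by_canon["O4'"]))
    if res.kind == "rna" and "O2'" in by_canon:
        fs.donors.append(_make_donor(by_canon["O2'"], adjacency))
        fs.acceptors.append(HBondAcceptor(by_canon["O2'"]))
    tpl = get_template(res.name)
    if tpl is None:  # modified nucleotide
        logger.warning("no template for nucleotide %s; generic perception",
                       res.label)
        return _perceive_generic(res.atoms, adjacency, cfg, fs)
    for name, _nh in tpl.donors.items():
        a = res.get_atom(name)
        if a is not None:
            fs.donors.append(_make_donor(a, adjacency))
    for name in tpl.acceptors:
        a = res.get_atom(name)
        if a is not None:
            fs.acceptors.append(HBondAcceptor(a))
    ring_atom_lists = [r for r in (_ring_from_names(res, names)
                                   for names in tpl.rings) if r is not None]
    system = (res.key, "base")
    for atoms in ring_atom_lists:
        fs.rings.append(AromaticRing(atoms, system_key=system,
                                     label=f"ring{len(atoms)}"))
    if len(ring_atom_lists) == 2:  # purine: fused-ring composite centroid
        union = list(dict.fromkeys(ring_atom_lists[0] + ring_atom_lists[1]))
        fs.rings.append(AromaticRing(union, system_key=system, label="fused"))
    _add_hydrophobics(fs, res.atoms, adjacency)
    return fs


# ---------------------------------------------------------------------------
# generic (ligand) perception

#: maximum C=O / C=N bond length used to call a double bond from geometry
_DOUBLE_BOND_CO = 1.30
#: aromatic/sp2 ring bond-length ceiling; saturated rings exceed it
_AROMATIC_BOND_MAX = 1.45


def ligand_polar_roles(atoms, adjacency) -> dict:
    """Per-atom polar roles of an arbitrary hetero group.

    Returns ``{atom: {"donor_h": int, "acceptor": bool, "charge": str}}``
    for N/O/S atoms, derived from element, heavy valence and the
    functional-group context. ``donor_h`` is the number of hydrogens the
    atom should carry at pH 7 (0 = not a donor).
    """
    atoms = [a for a in atoms if a.is_heavy]
    roles: dict = {}
    ring_atoms = set()
    for cycle in _heavy_cycles(atoms, adjacency):
        ring_atoms.update(cycle)

    def terminal_oxygens(center):
        return [o for o in heavy_neighbors(center, adjacency)
                if o.element == "O" and len(heavy_neighbors(o, adjacency)) == 1]

    guanidinium_n = set()
    for a in atoms:
        if a.element == "C":
            nbrs = heavy_neighbors(a, adjacency)
            n_nbrs = [n for n in nbrs if n.element == "N"
                      and len(heavy_neighbors(n, adjacency)) <= 2
                      and n not in ring_atoms]
            if len(nbrs) == 3 and len(n_nbrs) >= 2:
                guanidinium_n.update(n_nbrs)

    for a in atoms:
        if a.element not in ("N", "O", "S"):
            continue
        nbrs = heavy_neighbors(a, adjacency)
        k = len(nbrs)
        role = {"donor_h": 0, "acceptor": False, "charge": ""}
        if a.element == "O":
            if k == 0:
                role["acceptor"] = True
            elif k == 1:
                c = nbrs[0]
                if c.element in ("P", "S") and len(terminal_oxygens(c)) >= 2:
                    role["acceptor"] = True
                    role["charge"] = "negative-group"
                elif c.element == "C" and len(terminal_oxygens(c)) >= 2:
                    role["acceptor"] = True
                    role["charge"] = "negative-group"
                elif a.distance_to(c) <= _DOUBLE_BOND_CO:
                    role["acceptor"] = True        # carbonyl
                else:
                    role["donor_h"] = 1            # hydroxyl
                    role["acceptor"] = True
            elif k == 2:
                role["acceptor"] = True            # ether / ring oxygen
        elif a.element == "N":
            if a in guanidinium_n:
                role["donor_h"] = 3 - k
                role["charge"] = "positive-group"
            elif k == 4:
                role["charge"] = "positive"        # quaternary: never acceptor
            elif a in ring_atoms:
                if k == 2:
                    role["acceptor"] = True        # pyridine-like
                elif k == 2 or k == 3:
                    pass                           # substituted pyrrole-like
            else:
                amide = any(n.element == "C" and any(
                    o.element == "O" and len(heavy_neighbors(o, adjacency)) == 1
                    and o.distance_to(n) <= _DOUBLE_BOND_CO
                    for o in heavy_neighbors(n, adjacency)) for n in nbrs)
                imine = any(n.element == "C" and a.distance_to(n) <= 1.22
                            for n in nbrs)
                if imine and k == 1:
                    role["acceptor"] = True        # nitrile / imine N
                elif amide:
                    role["donor_h"] = max(0, 3 - k)
                elif all(n.element in ("C",) for n in nbrs) or k == 0:
                    # aliphatic amine: protonated at pH 7
                    role["donor_h"] = max(0, 4 - k)
                    role["charge"] = "positive"
                else:
                    role["donor_h"] = max(0, 3 - k)
        elif a.element == "S":
            if k == 1:
                role["donor_h"] = 1                # thiol
        roles[a] = role
    return roles


def _heavy_cycles(atoms, adjacency):
    """5- and 6-membered cycles of the heavy-atom bond graph, in cyclic order."""
    heavy = [a for a in atoms if a.is_heavy]
    g = nx.Graph()
    g.add_nodes_from(heavy)
    for a in heavy:
        for b in adjacency.get(a, ()):
            if b.is_heavy and b in g:
                g.add_edge(a, b)
    cycles = []
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        ordered = _order_cycle(cycle, g)
        if ordered is not None:
            cycles.append(ordered)
    return cycles


def _order_cycle(cycle_atoms, graph):
    sub = graph.subgraph(cycle_atoms)
    if any(sub.degree(a) != 2 for a in cycle_atoms):
        return None
    start = min(cycle_atoms, key=lambda a: a.serial)
    ordered = [start]
    prev = None
    while len(ordered) < len(cycle_atoms):
        nxt = [n for n in sub.neighbors(ordered[-1]) if n is not prev]
        prev = ordered[-1]
        ordered.append(nxt[0])
    return ordered


def _aromatic_rings(atoms, adjacency, cfg):
    """Rings by cycle perception + planarity + sp2 bond-length test; fused
    aromatic systems additionally contribute a composite centroid ring."""
    rings = []
    for ordered in _heavy_cycles(atoms, adjacency):
        if not all(a.element in ("C", "N", "O", "S") for a in ordered):
            continue
        bond_ok = all(
            ordered[i].distance_to(ordered[(i + 1) % len(ordered)])
            <= _AROMATIC_BOND_MAX for i in range(len(ordered)))
        if not bond_ok:
            continue
        _, _, rmsd = fit_plane([a.coords for a in ordered])
        if rmsd <= cfg.ring_planarity_max:
            rings.append(ordered)
    if not rings:
        return []
    # group fused rings (sharing >= 2 atoms) into one system
    rg = nx.Graph()
    rg.add_nodes_from(range(len(rings)))
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if len(set(rings[i]) & set(rings[j])) >= 2:
                rg.add_edge(i, j)
    out = []
    for comp in nx.connected_components(rg):
        comp = sorted(comp)
        key = (rings[comp[0]][0].parent.key,
               tuple(sorted(a.serial for i in comp for a in rings[i])))
        for i in comp:
            out.append(AromaticRing(rings[i], system_key=key,
                                    label=f"ring{len(rings[i])}"))
        if len(comp) > 1:
            union = list(dict.fromkeys(a for i in comp for a in rings[i]))
            _, _, rmsd = fit_plane([a.coords for a in union])
            if rmsd <= cfg.ring_planarity_max:
                out.append(AromaticRing(union, system_key=key, label="fused"))
    return out


def _perceive_generic(atoms, adjacency, cfg, fs):
    atoms = [a for a in atoms if a.is_heavy]
    roles = ligand_polar_roles(atoms, adjacency)
    for a, role in roles.items():
        if role["donor_h"] > 0:
            fs.donors.append(_make_donor(a, adjacency))
        if role["acceptor"]:
            fs.acceptors.append(HBondAcceptor(a))
        if role["charge"] == "positive":
            fs.pos_charges.append(
                ChargedCenter([a], "positive",
                              "quaternary" if len(heavy_neighbors(a, adjacency)) == 4
                              else "amine"))

    def terminal_oxygens(center):
        return [o for o in heavy_neighbors(center, adjacency)
                if o.element == "O" and len(heavy_neighbors(o, adjacency)) == 1]

    # charged functional groups
    for a in atoms:
        if a.element == "C":
            term = terminal_oxygens(a)
            nbrs = heavy_neighbors(a, adjacency)
            if len(term) >= 2:
                fs.neg_charges.append(ChargedCenter(term, "negative", "carboxylate"))
            n_nbrs = [n for n in nbrs if n.element == "N"
                      and len(heavy_neighbors(n, adjacency)) <= 2]
            if len(nbrs) == 3 and len(n_nbrs) == 3:
                fs.pos_charges.append(
                    ChargedCenter([a] + n_nbrs, "positive", "guanidinium"))
            elif len(nbrs) == 3 and len(n_nbrs) == 2 and not term:
                fs.pos_charges.append(
                    ChargedCenter([a] + n_nbrs, "positive", "amidinium"))
        elif a.element == "P":
            term = terminal_oxygens(a)
            if len(term) >= 2:
                fs.neg_charges.append(ChargedCenter(term, "negative", "phosphate"))
        elif a.element == "S":
            term = terminal_oxygens(a)
            if len(term) >= 2:
                fs.neg_charges.append(ChargedCenter(term, "negative", "sulfate"))
        elif a.element in METAL_SYMBOLS:
            fs.metals.append(MetalAtom(a))
        elif a.element in HALOGENS:
            nbrs = heavy_neighbors(a, adjacency)
            if len(nbrs) == 1 and nbrs[0].element == "C":
                if a.element != "F" or cfg.fluorine_as_donor:
                    fs.halogen_donors.append(HalogenDonor(a, nbrs[0]))
    fs.rings.extend(_aromatic_rings(atoms, adjacency, cfg))
    _add_hydrophobics(fs, atoms, adjacency)
    return fs


def perceive_ligand_features(ligand, adjacency,
                             cfg: Optional[ThresholdConfig] = None) -> FeatureSet:
    """Features of a ligand entity.

    Nucleic-chain and peptide ligands use the same residue templates as the
    receptor side; everything else goes through generic graph perception.
    """
    cfg = cfg or ThresholdConfig()
    fs = FeatureSet()
    for res in ligand.residues:
        if res.kind in ("amino_acid", "dna", "rna", "water", "metal_ion"):
            fs.extend(perceive_residue_features(res, adjacency, cfg))
        else:
            _perceive_generic(res.atoms, adjacency, cfg, fs)
    return fs
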