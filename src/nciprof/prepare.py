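"""Receptor/ligand splitting and binding-site construction.

A structure is partitioned into one receptor and a set of ligand entities.
Hetero residues not on the exclusion list become ligands; covalently
connected hetero residues merge into one composite entity. Nucleic residues
(U/A/C/G, DT/DA/DC/DG) follow the analysis mode: as receptor they are
excluded from ligand candidacy, otherwise each contiguous nucleic chain
becomes one nucleic-chain ligand. Waters never become ligands; they mediate
water bridges instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import AnalysisMode, ThresholdConfig
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

__all__ = ["LigandEntity", "BindingSite", "extract_ligands",
           "build_binding_site", "classify_receptor_scope",
           "ligand_from_chain"]

#: heavy-atom distance below which two residues are covalently linked when
#: no CONECT record says so (above C-C bond length, below clash distance)
COVALENT_MERGE_DIST = 1.9


@dataclass
class LigandEntity:
    residues: list
    composite: bool = False
    kind: str = "small_molecule"   # small_molecule | peptide | nucleic_chain | ion

    @property
    def identifier(self) -> str:
        primary = self.residues[0]
        chain = primary.chain_id if primary.chain_id.strip() else "_"
        return f"{primary.name}:{chain}:{primary.seq_number}"

    @property
    def chain_ids(self) -> set:
        return {r.chain_id for r in self.residues}

    def heavy_atoms(self) -> list:
        return [a for r in self.residues for a in r.atoms if a.is_heavy]

    def atoms(self) -> list:
        return [a for r in self.residues for a in r.atoms]

    def __repr__(self):
        return f"<LigandEntity {self.identifier} kind={self.kind} nres={len(self.residues)}>"


@dataclass
class BindingSite:
    ligand: LigandEntity
    receptor_residues: list = field(default_factory=list)
    waters: list = field(default_factory=list)

    @property
    def receptor_kind_summary(self) -> dict:
        counts = {"amino_acid": 0, "dna": 0, "rna": 0, "other": 0}
        for r in self.receptor_residues:
            counts[r.kind if r.kind in counts else "other"] += 1
        return counts

    @property
    def is_empty(self) -> bool:
        return not self.receptor_residues


def _covalently_linked(res_a: Residue, res_b: Residue, conect: dict) -> bool:
    serials_b = {a.serial for a in res_b.atoms}
    for a in res_a.heavy_atoms():
        if conect.get(a.serial, set()) & serials_b:
            return True
    for a in res_a.heavy_atoms():
        for b in res_b.heavy_atoms():
            if a.distance_to(b) < COVALENT_MERGE_DIST:
                return True
    return False


def _polymer_linked(res: Residue, residues: list, conect: dict) -> bool:
    """Is a hetero residue covalently linked into a polymer chain?"""
    for other in residues:
        if other is res:
            continue
        if other.kind in ("amino_acid", "dna", "rna") and \
                other.chain_id == res.chain_id and \
                abs(other.seq_number - res.seq_number) <= 1 and \
                _covalently_linked(res, other, conect):
            return True
    return False


def extract_ligands(structure: Structure, mode: AnalysisMode) -> list:
    """Ligand entities of the selected model under the given analysis mode."""
    residues = structure.residues()
    conect = structure.conect
    exclusions = set(mode.ligand_exclusion_list)

    candidates = []
    for res in residues:
        if res.kind == "water" or res.name.upper() in exclusions:
            continue
        if res.kind == "metal_ion":
            if mode.ions_as_ligands:
                candidates.append(res)
        elif res.is_nucleic:
            if not mode.nucleic_acids_as_receptor:
                candidates.append(res)
        elif res.kind == "other_hetero":
            if _polymer_linked(res, residues, conect) and \
                    not mode.modified_residues_as_ligand:
                continue  # modified residue stays in the receptor
            candidates.append(res)
        # amino acids stay in the receptor (peptide ligands are requested
        # explicitly via ligand_from_chain)

    if not candidates:
        logger.info("no ligand candidates found in structure")
        return []

    entities = []
    # contiguous nucleic runs per chain become one entity each
    nucleic = [r for r in candidates if r.is_nucleic]
    consumed = set()
    if nucleic:
        run: list = []
        for res in residues:
            if res in nucleic:
                if run and res.chain_id != run[-1].chain_id:
                    entities.append(_nucleic_entity(run))
                    run = []
                run.append(res)
                consumed.add(res)
            elif run and not res.is_nucleic and res.chain_id == run[-1].chain_id:
                entities.append(_nucleic_entity(run))
                run = []
        if run:
            entities.append(_nucleic_entity(run))

    rest = [r for r in candidates if r not in consumed]
    # merge covalently connected hetero residues into composites
    groups: list = []
    for res in rest:
        merged_into = None
        for group in groups:
            if any(_covalently_linked(res, other, conect) for other in group):
                if merged_into is None:
                    group.append(res)
                    merged_into = group
                else:  # res bridges two groups
                    merged_into.extend(group)
                    group.clear()
        if merged_into is None:
            groups.append([res])
    for group in groups:
        if not group:
            continue
        kinds = {r.kind for r in group}
        if kinds == {"metal_ion"} and len(group) == 1:
            kind = "ion"
        elif kinds <= {"amino_acid"}:
            kind = "peptide"
        else:
            kind = "small_molecule"
        entities.append(LigandEntity(group, composite=len(group) > 1, kind=kind))

    entities.sort(key=lambda e: (e.residues[0].chain_id,
                                 e.residues[0].seq_number,
                                 e.residues[0].name))
    return entities


def _nucleic_entity(run: list) -> LigandEntity:
    return LigandEntity(list(run), composite=len(run) > 1, kind="nucleic_chain")


def ligand_from_chain(structure: Structure, chain_id: str) -> LigandEntity:
    """Treat one whole polymer chain (peptide or nucleic) as the ligand."""
    residues = [r for r in structure.residues()
                if r.chain_id == chain_id and r.kind != "water"]
    if not residues:
        raise ValueError(f"no residues on chain {chain_id!r}")
    kinds = {r.kind for r in residues}
    kind = "nucleic_chain" if kinds & {"dna", "rna"} else "peptide"
    return LigandEntity(residues, composite=len(residues) > 1, kind=kind)


def build_binding_site(structure: Structure, ligand: LigandEntity,
                       cfg: ThresholdConfig = None,
                       cutoff: float = None) -> BindingSite:
    """Receptor residues with any heavy atom within the site shell of any
    ligand heavy atom, plus the waters in the same shell (for bridges)."""
    cfg = cfg or ThresholdConfig()
    cutoff = cutoff if cutoff is not None else cfg.binding_site_dist
    if cutoff <= 0:
        raise ValueError("binding-site cutoff must be positive")
    lig_coords = np.array([a.coords for a in ligand.heavy_atoms()])
    site = BindingSite(ligand)
    if lig_coords.size == 0:
        return site
    tree = cKDTree(lig_coords)
    lig_residues = set(ligand.residues)
    for res in structure.residues():
        if res in lig_residues:
            continue
        coords = [a.coords for a in res.heavy_atoms()]
        if not coords:
            continue
        dmin = tree.query(np.asarray(coords), k=1)[0].min()
        if dmin <= cutoff:
            if res.kind == "water":
                site.waters.append(res)
            else:
                site.receptor_residues.append(res)
    return site


def classify_receptor_scope(site: BindingSite, mode: AnalysisMode) -> BindingSite:
    """Drop same-chain receptor residues for chain ligands when intra-chain
    analysis is disabled; identity otherwise."""
    if mode.intra_chain or site.ligand.kind not in ("peptide", "nucleic_chain"):
        return site
    own = site.ligand.chain_ids
    site.receptor_residues = [r for r in site.receptor_residues
                              if r.chain_id not in own]
    return site
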