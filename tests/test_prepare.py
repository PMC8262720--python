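"""Receptor/ligand splitting, binding sites and analysis-mode scope."""

import numpy as np
import pytest

from nciprof.config import AnalysisMode, ThresholdConfig
from nciprof.fixtures import (_Builder, _ala_contact, _guanine, _uracil, _X)
from nciprof.prepare import (build_binding_site, classify_receptor_scope,
                             extract_ligands, ligand_from_chain)
from nciprof.structure import parse_pdb


def _protein_plus_rna():
    """Three protein residues (chain A) near a 5-residue RNA chain (UGGUG,
    chain R)."""
    b = _Builder()
    for i, resname in enumerate(["U", "G", "G", "U", "G"], start=1):
        origin = np.array([12.0 * (i - 1), 0.0, 0.0])
        if resname == "G":
            _guanine(b, origin, "R", i, resname="G")
        else:
            _uracil(b, origin, "R", i)
    for i in range(3):
        _ala_contact(b, np.array([12.0 * i, 0.0, 5.0]), _X, "A", 100 + i)
    b.quantize()
    return parse_pdb(b.to_pdb())


def _protein_plus_hetero(dist=5.0, resname="ATP"):
    b = _Builder()
    b.add("C1", "C", np.zeros(3), resname, "L", 1, True)
    b.add("O1", "O", np.array([1.4, 0.0, 0.0]), resname, "L", 1, True)
    _ala_contact(b, np.array([0.0, 0.0, dist]), _X, "A", 1)
    b.quantize()
    return parse_pdb(b.to_pdb())


def test_single_hetero_group_is_one_small_molecule():
    s = _protein_plus_hetero()
    ligs = extract_ligands(s, AnalysisMode())
    assert len(ligs) == 1
    assert ligs[0].kind == "small_molecule"
    assert ligs[0].identifier == "ATP:L:1"


def test_excluded_buffer_molecules_are_not_ligands():
    s = _protein_plus_hetero(resname="GOL")
    assert extract_ligands(s, AnalysisMode()) == []
    # restoring them via the exclusion list works
    mode = AnalysisMode(ligand_exclusion_list=())
    assert len(extract_ligands(s, mode)) == 1


def test_waters_are_never_ligand_entities():
    b = _Builder()
    b.add("O", "O", np.zeros(3), "HOH", "W", 1, True)
    _ala_contact(b, np.array([0.0, 0.0, 5.0]), _X, "A", 1)
    s = parse_pdb(b.to_pdb())
    assert extract_ligands(s, AnalysisMode()) == []


def test_rna_chain_becomes_one_nucleic_ligand_in_ligand_mode():
    s = _protein_plus_rna()
    ligs = extract_ligands(
        s, AnalysisMode(nucleic_acids_as_receptor=False))
    assert len(ligs) == 1
    (lig,) = ligs
    assert lig.kind == "nucleic_chain"
    assert len(lig.residues) == 5
    assert [r.name for r in lig.residues] == ["U", "G", "G", "U", "G"]


def test_nucleic_receptor_mode_moves_rna_into_receptor():
    s = _protein_plus_rna()
    mode = AnalysisMode(nucleic_acids_as_receptor=True)
    assert extract_ligands(s, mode) == []
    # the RNA residues appear in a binding site's receptor set instead
    peptide = ligand_from_chain(s, "A")
    site = build_binding_site(s, peptide)
    assert site.receptor_kind_summary["rna"] > 0


def test_mode_flip_covers_the_same_residue_set():
    """The nucleic residues seen as receptor in one mode are exactly the
    nucleic ligand residues of the other mode."""
    s = _protein_plus_rna()
    as_ligand = extract_ligands(
        s, AnalysisMode(nucleic_acids_as_receptor=False))
    lig_residues = {r.key for e in as_ligand for r in e.residues
                    if r.is_nucleic}
    receptor_nucleic = {r.key for r in s.residues() if r.is_nucleic}
    assert lig_residues == receptor_nucleic


def test_covalently_linked_hetero_residues_merge_into_composite():
    b = _Builder()
    b.add("C1", "C", np.zeros(3), "AAA", "L", 1, True)
    b.add("C1", "C", np.array([1.5, 0.0, 0.0]), "BBB", "L", 2, True)
    b.add("C1", "C", np.array([20.0, 0.0, 0.0]), "CCC", "L", 3, True)
    _ala_contact(b, np.array([0.0, 0.0, 5.0]), _X, "A", 1)
    s = parse_pdb(b.to_pdb())
    ligs = extract_ligands(s, AnalysisMode())
    by_id = {e.identifier: e for e in ligs}
    assert len(ligs) == 2
    assert by_id["AAA:L:1"].composite
    assert len(by_id["AAA:L:1"].residues) == 2
    assert not by_id["CCC:L:3"].composite


@pytest.mark.parametrize("dist,included", [(7.0, True), (7.5, True),
                                           (8.0, False)])
def test_binding_site_shell_is_inclusive(dist, included):
    """Brute-force oracle: a residue is in the site iff some heavy-atom
    pair is within the (inclusive) cutoff."""
    s = _protein_plus_hetero(dist=dist)
    (lig,) = extract_ligands(s, AnalysisMode())
    site = build_binding_site(s, lig, ThresholdConfig())
    # independent check: min pairwise heavy-atom distance
    rec_res = [r for r in s.residues() if r.chain_id == "A"]
    dmin = min(a.distance_to(b) for r in rec_res for a in r.heavy_atoms()
               for b in lig.heavy_atoms())
    assert (dmin <= 7.5) == included
    assert bool(site.receptor_residues) == included
    if not included:
        assert site.is_empty  # empty site is not an error


def test_enlarging_the_cutoff_never_removes_residues():
    s = _protein_plus_rna()
    lig = ligand_from_chain(s, "R")
    prev = set()
    for cutoff in (3.0, 5.0, 7.5, 10.0):
        site = build_binding_site(s, lig, cutoff=cutoff)
        cur = {r.key for r in site.receptor_residues}
        assert prev <= cur
        prev = cur


def test_receptor_and_ligand_atom_sets_are_disjoint():
    for struct in (_protein_plus_rna(), _protein_plus_hetero()):
        for mode in (AnalysisMode(), AnalysisMode(nucleic_acids_as_receptor=True)):
            for lig in extract_ligands(struct, mode):
                site = build_binding_site(struct, lig)
                lig_atoms = {id(a) for a in lig.atoms()}
                rec_atoms = {id(a) for r in site.receptor_residues
                             for a in r.atoms}
                assert not (lig_atoms & rec_atoms)


def test_intra_chain_scope_for_chain_ligands():
    s = _protein_plus_rna()
    # make one protein residue share the RNA's chain id
    lig = ligand_from_chain(s, "R")
    site = build_binding_site(s, lig)
    n_before = len(site.receptor_residues)
    assert n_before > 0
    # intra-chain enabled: identity
    same = classify_receptor_scope(site, AnalysisMode(intra_chain=True))
    assert len(same.receptor_residues) == n_before

    # a receptor residue on the ligand's own chain is removed when disabled
    b = _Builder()
    _uracil(b, np.zeros(3), "R", 1)
    _ala_contact(b, np.array([0.0, 0.0, 5.0]), _X, "R", 50)  # same chain
    _ala_contact(b, np.array([0.0, 0.0, -5.0]), _X, "A", 60)
    s2 = parse_pdb(b.to_pdb())
    lig2 = ligand_from_chain(s2, "R")
    # ligand_from_chain grabs the whole chain; restrict to the nucleic residue
    lig2.residues = [r for r in lig2.residues if r.is_nucleic]
    site2 = build_binding_site(s2, lig2)
    assert {r.chain_id for r in site2.receptor_residues} == {"R", "A"}
    scoped = classify_receptor_scope(site2, AnalysisMode(intra_chain=False))
    assert {r.chain_id for r in scoped.receptor_residues} == {"A"}


def test_small_molecule_ligand_ignores_intra_chain_rule():
    s = _protein_plus_hetero()
    (lig,) = extract_ligands(s, AnalysisMode())
    site = build_binding_site(s, lig)
    n = len(site.receptor_residues)
    scoped = classify_receptor_scope(site, AnalysisMode(intra_chain=False))
    assert len(scoped.receptor_residues) == n
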