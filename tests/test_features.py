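"""Functional characterisation: template and graph-based feature perception."""

import numpy as np
import pytest

from nciprof.bonds import perceive_bonds
from nciprof.config import AnalysisMode, ThresholdConfig
from nciprof.features import (ligand_polar_roles, perceive_ligand_features,
                              perceive_residue_features)
from nciprof.fixtures import (_Builder, _arg_guanidinium, _benzene, _guanine,
                              _lys_cation, _phe_ring, _pyrazine, _uracil, _X,
                              _Y, _Z)
from nciprof.hydrogens import ensure_hydrogens
from nciprof.prepare import extract_ligands
from nciprof.structure import parse_pdb


def _perceive_first(pdb_text, hydrogenate=True):
    s = parse_pdb(pdb_text)
    if hydrogenate:
        ensure_hydrogens(s)
    adjacency = perceive_bonds(list(s.atoms()), s.conect)
    res = s.residues()[0]
    return res, perceive_residue_features(res, adjacency), s, adjacency


def _asp_pdb():
    b = _Builder()
    n = np.array([0.0, 1.4, 0.0])
    b.add("N", "N", n, "ASP", "A", 1, False)
    b.add("CA", "C", [0.0, 0.0, 0.0], "ASP", "A", 1, False)
    b.add("C", "C", [1.3, -0.7, 0.0], "ASP", "A", 1, False)
    b.add("O", "O", [2.4, -0.1, 0.0], "ASP", "A", 1, False)
    b.add("CB", "C", [-1.2, -0.8, 0.0], "ASP", "A", 1, False)
    b.add("CG", "C", [-2.5, -0.1, 0.0], "ASP", "A", 1, False)
    b.add("OD1", "O", [-3.5, -0.8, 0.3], "ASP", "A", 1, False)
    b.add("OD2", "O", [-2.7, 1.1, -0.3], "ASP", "A", 1, False)
    return b.to_pdb()


def test_aspartate_has_one_negative_center_over_both_carboxylate_oxygens():
    res, fs, _, _ = _perceive_first(_asp_pdb())
    assert len(fs.neg_charges) == 1
    (neg,) = fs.neg_charges
    assert {a.name for a in neg.atoms} == {"OD1", "OD2"}
    od1 = res.get_atom("OD1")
    od2 = res.get_atom("OD2")
    assert np.allclose(neg.centroid, (od1.coords + od2.coords) / 2)
    assert fs.pos_charges == []
    # side-chain carboxylate oxygens are also acceptors
    assert {"OD1", "OD2"} <= {a.acceptor_atom.name for a in fs.acceptors}


def test_phenylalanine_one_ring_no_charges():
    b = _Builder()
    _phe_ring(b, np.zeros(3), _Z, "A", 1)
    res, fs, _, _ = _perceive_first(b.to_pdb())
    assert len(fs.rings) == 1
    assert len(fs.rings[0].atoms) == 6
    assert fs.rings[0].planarity_rmsd <= 0.25
    assert fs.pos_charges == [] and fs.neg_charges == []


def test_arginine_carries_cationic_guanidinium_group():
    b = _Builder()
    _arg_guanidinium(b, np.zeros(3), _Y, _X, _Z, "A", 1)
    _, fs, _, _ = _perceive_first(b.to_pdb())
    assert len(fs.pos_charges) == 1
    (pos,) = fs.pos_charges
    assert {a.name for a in pos.atoms} == {"CZ", "NH1", "NH2", "NE"}
    assert pos.is_guanidinium
    assert {"NE", "NH1", "NH2"} <= {d.donor_atom.name for d in fs.donors}


def test_guanine_rings_and_donor_acceptor_template():
    b = _Builder()
    _guanine(b, np.zeros(3), "R", 1, resname="DG", with_phosphate=True)
    res, fs, _, _ = _perceive_first(b.to_pdb())
    assert res.kind == "dna"
    # purine: 6-ring, 5-ring and the fused composite
    assert len(fs.rings) >= 2
    labels = {r.label for r in fs.rings}
    assert "fused" in labels
    assert len({r.system_key for r in fs.rings}) == 1
    acceptor_names = {a.acceptor_atom.name for a in fs.acceptors}
    assert {"O6", "N3", "N7"} <= acceptor_names
    donor_names = {d.donor_atom.name for d in fs.donors}
    assert {"N1", "N2"} <= donor_names
    # phosphate: one negative centre over the two free phosphate oxygens
    assert len(fs.neg_charges) == 1
    assert {a.name for a in fs.neg_charges[0].atoms} == {"OP1", "OP2"}


def test_thymine_methyl_is_hydrophobic_uracil_has_no_methyl():
    b = _Builder()
    _uracil(b, np.zeros(3), "D", 1, resname="DT", with_c7=True)
    _, fs_dt, _, _ = _perceive_first(b.to_pdb())
    assert "C7" in {h.atom.name for h in fs_dt.hydrophobics}

    b2 = _Builder()
    _uracil(b2, np.zeros(3), "R", 1, resname="U")
    _, fs_u, _, _ = _perceive_first(b2.to_pdb())
    assert "C7" not in {h.atom.name for h in fs_u.hydrophobics}


def _ligand_features(pdb_text, mode=None):
    s = parse_pdb(pdb_text)
    ensure_hydrogens(s)
    adjacency = perceive_bonds(list(s.atoms()), s.conect)
    (lig,) = extract_ligands(s, mode or AnalysisMode())
    return lig, perceive_ligand_features(lig, adjacency), adjacency


def test_benzene_ligand_ring_and_hydrophobics_no_donors():
    b = _Builder()
    _benzene(b, np.zeros(3), _Z, "L", 1)
    _, fs, _ = _ligand_features(b.to_pdb())
    assert len(fs.rings) == 1
    assert len(fs.hydrophobics) == 6
    assert fs.donors == [] and fs.acceptors == []


def test_chlorobenzene_ligand_has_one_halogen_donor():
    b = _Builder()
    ring = _benzene(b, np.zeros(3), _Z, "L", 1)
    c1 = ring[0]
    out = c1.coords / np.linalg.norm(c1.coords)
    b.add("Cl", "CL", c1.coords + 1.74 * out, "LIG", "L", 1, True)
    _, fs, _ = _ligand_features(b.to_pdb())
    assert len(fs.halogen_donors) == 1
    assert fs.halogen_donors[0].carbon is not None
    # the halogen-bearing carbon is no longer hydrophobic
    assert len(fs.hydrophobics) == 5


def test_fluorine_is_not_a_halogen_donor_by_default():
    b = _Builder()
    ring = _benzene(b, np.zeros(3), _Z, "L", 1)
    c1 = ring[0]
    out = c1.coords / np.linalg.norm(c1.coords)
    b.add("F1", "F", c1.coords + 1.35 * out, "LIG", "L", 1, True)
    s = parse_pdb(b.to_pdb())
    adjacency = perceive_bonds(list(s.atoms()), s.conect)
    (lig,) = extract_ligands(s, AnalysisMode())
    fs = perceive_ligand_features(lig, adjacency, ThresholdConfig())
    assert fs.halogen_donors == []
    fs2 = perceive_ligand_features(
        lig, adjacency, ThresholdConfig().replace(fluorine_as_donor=True))
    assert len(fs2.halogen_donors) == 1


def test_pyrazine_nitrogens_are_acceptors_not_donors():
    b = _Builder()
    _pyrazine(b, np.zeros(3), _Z, "L", 1)
    _, fs, _ = _ligand_features(b.to_pdb())
    assert len(fs.rings) == 1
    assert len(fs.acceptors) == 2
    assert fs.donors == []
    assert fs.hydrophobics == []   # every ring C has an N neighbour


def test_saturated_ring_is_not_aromatic():
    """Cyclohexane (chair, 1.54 A bonds) must not register as a ring."""
    b = _Builder()
    import math
    for k in range(6):
        ang = math.radians(60 * k)
        z = 0.25 if k % 2 == 0 else -0.25
        b.add(f"C{k + 1}", "C", [1.47 * math.cos(ang),
                                 1.47 * math.sin(ang), z],
              "LIG", "L", 1, True)
    _, fs, _ = _ligand_features(b.to_pdb())
    assert fs.rings == []


def test_quaternary_nitrogen_is_charged_but_never_an_acceptor():
    b = _Builder()
    b.add("N1", "N", [0.0, 0.0, 0.0], "LIG", "L", 1, True)
    for i, d in enumerate([(1.5, 0, 0), (-1.5, 0, 0), (0, 1.5, 0),
                           (0, -1.5, 0)], start=1):
        b.add(f"C{i}", "C", d, "LIG", "L", 1, True)
    _, fs, _ = _ligand_features(b.to_pdb())
    assert len(fs.pos_charges) == 1
    assert fs.pos_charges[0].label == "quaternary"
    assert all(a.acceptor_atom.element != "N" for a in fs.acceptors)
    assert fs.donors == []


def test_carboxylate_and_amine_roles_in_glycine_like_zwitterion():
    """Generic perception of a glycine-like hetero ligand: carboxylate
    negative centre, protonated amine positive centre."""
    b = _Builder()
    b.add("N1", "N", [-1.47, 0.0, 0.0], "LIG", "L", 1, True)
    b.add("CA", "C", [0.0, 0.0, 0.0], "LIG", "L", 1, True)
    b.add("C1", "C", [0.8, 1.3, 0.0], "LIG", "L", 1, True)
    b.add("O1", "O", [2.03, 1.3, 0.3], "LIG", "L", 1, True)
    b.add("O2", "O", [0.2, 2.4, -0.3], "LIG", "L", 1, True)
    _, fs, _ = _ligand_features(b.to_pdb())
    assert len(fs.neg_charges) == 1
    assert {a.name for a in fs.neg_charges[0].atoms} == {"O1", "O2"}
    assert len(fs.pos_charges) == 1
    assert fs.pos_charges[0].atoms[0].name == "N1"


def test_feature_sets_are_order_independent():
    """Shuffling atom input order changes no perceived feature sets."""
    b = _Builder()
    _guanine(b, np.zeros(3), "R", 1, resname="G")
    s = parse_pdb(b.to_pdb())
    ensure_hydrogens(s)
    adjacency = perceive_bonds(list(s.atoms()), s.conect)
    res = s.residues()[0]
    fs1 = perceive_residue_features(res, adjacency)
    rng = np.random.default_rng(7)
    res.atoms = [res.atoms[i] for i in rng.permutation(len(res.atoms))]
    fs2 = perceive_residue_features(res, adjacency)

    def sig(fs):
        return (
            sorted(d.donor_atom.serial for d in fs.donors),
            sorted(a.acceptor_atom.serial for a in fs.acceptors),
            sorted(frozenset(a.serial for a in c.atoms)
                   for c in fs.neg_charges),
            sorted((frozenset(a.serial for a in r.atoms) for r in fs.rings),
                   key=sorted),
            sorted(h.atom.serial for h in fs.hydrophobics),
        )
    assert sig(fs1) == sig(fs2)


def test_ring_normal_is_stable_up_to_sign_under_atom_reversal():
    b = _Builder()
    ring = _benzene(b, np.zeros(3), _Z, "L", 1)
    _, fs, _ = _ligand_features(b.to_pdb())
    from nciprof.geometry import fit_plane, plane_angle_deg
    _, n_fwd, _ = fit_plane([a.coords for a in fs.rings[0].atoms])
    _, n_rev, _ = fit_plane([a.coords for a in reversed(fs.rings[0].atoms)])
    assert plane_angle_deg(n_fwd, n_rev) < 1e-6
    del ring


def test_no_atom_is_both_donor_hydrogen_and_hydrophobic():
    for pdb in (_asp_pdb(),):
        s = parse_pdb(pdb)
        ensure_hydrogens(s)
        adjacency = perceive_bonds(list(s.atoms()), s.conect)
        res = s.residues()[0]
        fs = perceive_residue_features(res, adjacency)
        h_serials = {h.serial for d in fs.donors for h in d.hydrogens}
        hydroph = {h.atom.serial for h in fs.hydrophobics}
        assert not (h_serials & hydroph)


def test_rdkit_agrees_on_ligand_ring_perception():
    """Independent cross-check of cycle perception on a fused aromatic
    system (naphthalene-like)."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem
    mol = Chem.MolFromSmiles("c1ccc2ccccc2c1")
    mol = Chem.AddHs(mol)
    from rdkit.Chem import AllChem
    AllChem.EmbedMolecule(mol, randomSeed=11)
    conf = mol.GetConformer()
    b = _Builder()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        p = conf.GetAtomPosition(atom.GetIdx())
        b.add(f"C{atom.GetIdx() + 1}", "C", [p.x, p.y, p.z], "LIG", "L", 1,
              True)
    b.quantize()
    _, fs, _ = _ligand_features(b.to_pdb())
    plain = [r for r in fs.rings if r.label != "fused"]
    assert len(plain) == mol.GetRingInfo().NumRings()
    assert len({r.system_key for r in fs.rings}) == 1
    assert any(r.label == "fused" for r in fs.rings)
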