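"""Geometric detectors: rule examples, properties and refinement."""

import math

import numpy as np
import pytest

import microgeo
from equivalence import DETECTORS, compare_one
from nciprof.config import ThresholdConfig
from nciprof.detect import (HydrogenBond, classify_coordination,
                            detect_hbonds, detect_hydrophobic,
                            detect_metal_complexes, detect_pication,
                            detect_pistacking, detect_salt_bridges,
                            detect_water_bridges, refine_interactions)
from nciprof.features import (AromaticRing, ChargedCenter, FeatureSet,
                              HBondAcceptor, HBondDonor, HydrophobicAtom,
                              MetalAtom, WaterOxygen)
from microgeo import Counter, make_atom, make_residue

CFG = ThresholdConfig()


def _carbon_pair(dist):
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig_res = make_residue()
    rec_res = make_residue("ALA", "amino_acid", "A", 1)
    lig.hydrophobics.append(HydrophobicAtom(make_atom(c, lig_res)))
    rec.hydrophobics.append(
        HydrophobicAtom(make_atom(c, rec_res, coords=(dist, 0, 0))))
    return lig, rec


@pytest.mark.parametrize("dist,n", [(3.8, 1), (4.0, 1), (4.2, 0)])
def test_hydrophobic_distance_rule_is_inclusive(dist, n):
    assert len(detect_hydrophobic(*_carbon_pair(dist), CFG)) == n


def _hbond_pair(dist, angle):
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig_res = make_residue()
    rec_res = make_residue("ALA", "amino_acid", "A", 1)
    d = make_atom(c, lig_res, element="N", coords=(0, 0, 0))
    # H in the xy-plane such that the D-H...A angle equals ``angle``
    acc_pos = np.array([dist, 0.0, 0.0])
    best = None
    for phi in np.linspace(0, math.pi, 20000):
        h = np.array([math.cos(phi), math.sin(phi), 0.0])
        u = -h
        v = acc_pos - h
        ang = math.degrees(math.acos(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
        if best is None or abs(ang - angle) < best[0]:
            best = (abs(ang - angle), h)
    h = make_atom(c, lig_res, element="H", coords=best[1])
    lig.donors.append(HBondDonor(d, [h]))
    rec.acceptors.append(
        HBondAcceptor(make_atom(c, rec_res, element="O", coords=acc_pos)))
    return lig, rec


@pytest.mark.parametrize("dist,angle,n", [
    (2.9, 165.0, 1),   # canonical hydrogen bond
    (2.9, 80.0, 0),    # donor angle below the minimum
    (4.3, 165.0, 0),   # heavy-atom distance beyond the cutoff
])
def test_hbond_distance_and_angle_rule(dist, angle, n):
    lig, rec = _hbond_pair(dist, angle)
    bonds = detect_hbonds(lig, rec, CFG)
    assert len(bonds) == n
    if bonds:
        assert bonds[0].donor_is_ligand
        assert abs(bonds[0].dist_da - dist) < 1e-6


def test_donor_without_hydrogen_is_flagged_distance_only():
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    d = make_atom(c, make_residue(), element="N")
    lig.donors.append(HBondDonor(d, [], missing_h=True))
    rec.acceptors.append(HBondAcceptor(
        make_atom(c, make_residue("ALA", "amino_acid", "A", 1), element="O",
                  coords=(2.9, 0, 0))))
    (hb,) = detect_hbonds(lig, rec, CFG)
    assert hb.unverified and hb.angle is None


def _bridge(leg1=2.8, leg2=2.8, omega=110.0):
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig_res = make_residue()
    rec_res = make_residue("SER", "amino_acid", "A", 1)
    don = make_atom(c, lig_res, element="O", coords=(0, 0, 0))
    h = make_atom(c, lig_res, element="H", coords=(1, 0, 0))
    lig.donors.append(HBondDonor(don, [h]))
    w = make_atom(c, make_residue("HOH", "water", "W", 9), element="O",
                  coords=(leg1, 0, 0))
    rad = math.radians(omega)
    acc_pos = w.coords + leg2 * np.array([-math.cos(rad), math.sin(rad), 0])
    rec.acceptors.append(
        HBondAcceptor(make_atom(c, rec_res, element="O", coords=acc_pos)))
    return lig, rec, [WaterOxygen(w)]


@pytest.mark.parametrize("leg1,leg2,omega,n", [
    (2.8, 2.8, 110.0, 1),
    (4.5, 2.8, 110.0, 0),   # one leg beyond the window
    (2.8, 2.8, 60.0, 0),    # omega below the window
    (2.5, 4.1, 75.0, 1),    # inclusive at every boundary
])
def test_water_bridge_window_rule(leg1, leg2, omega, n):
    lig, rec, waters = _bridge(leg1, leg2, omega)
    found = detect_water_bridges(lig, rec, waters, CFG)
    assert len(found) == n
    if found:
        assert found[0].donor_is_ligand


def _salt(dist, lig_sign="negative"):
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig_res = make_residue()
    rec_res = make_residue("LYS", "amino_acid", "A", 1)
    l_atoms = [make_atom(c, lig_res, element="O", coords=(0, 0.8, 0)),
               make_atom(c, lig_res, element="O", coords=(0, -0.8, 0))]
    lc = ChargedCenter(l_atoms, lig_sign, "carboxylate")
    (lig.neg_charges if lig_sign == "negative" else lig.pos_charges).append(lc)
    r_atom = make_atom(c, rec_res, element="N", coords=(dist, 0, 0))
    rec.pos_charges.append(ChargedCenter([r_atom], "positive", "ammonium"))
    return lig, rec


@pytest.mark.parametrize("dist,n", [(4.0, 1), (5.5, 1), (6.0, 0)])
def test_salt_bridge_centroid_distance(dist, n):
    assert len(detect_salt_bridges(*_salt(dist), CFG)) == n


def test_like_charges_never_form_a_salt_bridge():
    lig, rec = _salt(3.0, lig_sign="positive")
    assert detect_salt_bridges(lig, rec, CFG) == []


def _ring_at(counter, res, center, normal):
    center = np.asarray(center, float)
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    u = np.cross(normal, [0, 0, 1.0] if abs(normal[2]) < 0.9 else [1.0, 0, 0])
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = [make_atom(counter, res,
                       coords=center + 1.39 * (math.cos(a) * u
                                               + math.sin(a) * v))
             for a in np.linspace(0, 2 * math.pi, 7)[:-1]]
    return AromaticRing(atoms)


@pytest.mark.parametrize("dz,offset,tilt,expect", [
    (3.8, 0.5, 0.0, "P"),     # coplanar parallel stack
    (5.0, 1.0, 90.0, "T"),    # perpendicular T-stack
    (5.0, 0.5, 45.0, None),   # outside both angular windows
    (5.6, 0.0, 0.0, None),    # centroid distance beyond cutoff
    (3.8, 2.3, 0.0, None),    # lateral offset beyond cutoff
])
def test_pistacking_angle_and_offset_windows(dz, offset, tilt, expect):
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig.rings.append(_ring_at(c, make_residue(), (0, 0, 0), (0, 0, 1)))
    h = math.sqrt(max(dz ** 2 - offset ** 2, 0))
    rad = math.radians(tilt)
    rec.rings.append(_ring_at(
        c, make_residue("PHE", "amino_acid", "A", 1), (offset, 0, h),
        (math.sin(rad), 0, math.cos(rad))))
    found = detect_pistacking(lig, rec, CFG)
    if expect is None:
        assert found == []
    else:
        assert len(found) == 1 and found[0].stack_type == expect


@pytest.mark.parametrize("along_normal,n", [(True, 1), (False, 0)])
def test_pication_face_on_rule_for_guanidinium(along_normal, n):
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig.rings.append(_ring_at(c, make_residue(), (0, 0, 0), (0, 0, 1)))
    pos = (0, 0, 4.0) if along_normal else (4.0, 0, 0)
    cation = ChargedCenter(
        [make_atom(c, make_residue("ARG", "amino_acid", "A", 1),
                   element="N", coords=pos)], "positive", "guanidinium")
    rec.pos_charges.append(cation)
    assert len(detect_pication(lig, rec, CFG)) == n


def test_non_guanidinium_cation_in_plane_still_counts():
    """The face-on restriction applies to guanidinium groups only."""
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig.rings.append(_ring_at(c, make_residue(), (0, 0, 0), (0, 0, 1)))
    rec.pos_charges.append(ChargedCenter(
        [make_atom(c, make_residue("LYS", "amino_acid", "A", 1),
                   element="N", coords=(4.0, 0, 0))], "positive", "ammonium"))
    assert len(detect_pication(lig, rec, CFG)) == 1


def test_metal_coordination_geometry_labels():
    octa = [(2.1, 0, 0), (-2.1, 0, 0), (0, 2.1, 0), (0, -2.1, 0),
            (0, 0, 2.1), (0, 0, -2.1)]
    label, rmsd = classify_coordination((0, 0, 0), octa)
    assert label == "octahedral" and rmsd < 1e-6
    s = 2.1 / math.sqrt(3)
    tetra = [(s, s, s), (s, -s, -s), (-s, s, -s), (-s, -s, s)]
    assert classify_coordination((0, 0, 0), tetra)[0] == "tetrahedral"
    square = [(2.1, 0, 0), (-2.1, 0, 0), (0, 2.1, 0), (0, -2.1, 0)]
    assert classify_coordination((0, 0, 0), square)[0] == "square.planar"
    assert classify_coordination((0, 0, 0), [(2.1, 0, 0)])[0] \
        == "other/underdetermined"


def test_metal_complex_records_full_sphere():
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    m = MetalAtom(make_atom(c, make_residue("MG", "metal_ion"), element="MG"))
    lig.metals.append(m)
    rec_res = make_residue("ASP", "amino_acid", "A", 1)
    for d in [(2.1, 0, 0), (-2.1, 0, 0), (0, 2.1, 0), (0, -2.1, 0),
              (0, 0, 2.1), (0, 0, -2.1)]:
        rec.acceptors.append(
            HBondAcceptor(make_atom(c, rec_res, element="O", coords=d)))
    records = detect_metal_complexes(lig, rec, [], CFG)
    assert len(records) == 6
    assert all(r.geometry_label == "octahedral" for r in records)
    assert all(r.coordination_number == 6 for r in records)


def test_zinc_beyond_cutoff_is_not_coordinated():
    c = Counter()
    lig = FeatureSet()
    rec = FeatureSet()
    lig.metals.append(MetalAtom(
        make_atom(c, make_residue("ZN", "metal_ion"), element="ZN")))
    rec.acceptors.append(HBondAcceptor(make_atom(
        c, make_residue("ASP", "amino_acid", "A", 1), element="O",
        coords=(3.4, 0, 0))))
    assert detect_metal_complexes(lig, rec, [], CFG) == []


# ---------------------------------------------------------------------------
# refinement

def test_salt_bridge_subsumes_member_hydrogen_bonds():
    lig, rec = _salt(3.5)
    # give the receptor ammonium a hydrogen pointing at a carboxylate O
    c = Counter()
    c.n = 100
    nz = rec.pos_charges[0].atoms[0]
    h = make_atom(c, nz.parent, element="H",
                  coords=nz.coords + (np.array([0, 0.8, 0]) - nz.coords) / 3.5)
    rec.donors.append(HBondDonor(nz, [h]))
    lig.acceptors.extend(HBondAcceptor(a) for a in lig.neg_charges[0].atoms)
    raw = {
        "hbond": detect_hbonds(lig, rec, CFG),
        "salt_bridge": detect_salt_bridges(lig, rec, CFG),
    }
    assert raw["hbond"] and raw["salt_bridge"]
    refined = refine_interactions(raw, CFG)
    assert refined["salt_bridge"] and refined["hbond"] == []


def test_unrelated_hydrogen_bond_survives_salt_bridge_refinement():
    lig, rec = _salt(3.5)
    lig.acceptors.extend(HBondAcceptor(a) for a in lig.neg_charges[0].atoms)
    c = Counter()
    c.n = 200
    # an independent donor elsewhere in the site
    other_res = make_residue("SER", "amino_acid", "A", 5)
    d = make_atom(c, other_res, element="O", coords=(0, 10.0, 0))
    h = make_atom(c, other_res, element="H", coords=(0, 9.0, 0))
    rec.donors.append(HBondDonor(d, [h]))
    lig.acceptors.append(HBondAcceptor(
        make_atom(c, make_residue(), element="O", coords=(0, 7.2, 0))))
    raw = {"hbond": detect_hbonds(lig, rec, CFG),
           "salt_bridge": detect_salt_bridges(lig, rec, CFG)}
    refined = refine_interactions(raw, CFG)
    assert len(refined["hbond"]) == 1
    assert refined["hbond"][0].donor.serial == d.serial


def test_direct_hbond_suppresses_water_bridge_for_same_pair():
    lig, rec, waters = _bridge()
    don = lig.donors[0].donor_atom
    acc = rec.acceptors[0].acceptor_atom
    fake_direct = HydrogenBond(don, acc, lig.donors[0].hydrogens[0],
                               3.0, 2.1, 150.0, donor_is_ligand=True)
    raw = {"hbond": [fake_direct],
           "water_bridge": detect_water_bridges(lig, rec, waters, CFG)}
    assert raw["water_bridge"]
    refined = refine_interactions(raw, CFG)
    assert refined["water_bridge"] == []


def test_purine_multi_ring_stack_reports_once():
    """Both rings of a fused system stacking one PHE ring collapse to the
    best-offset record."""
    c = Counter()
    lig_res = make_residue("G", "rna", "R", 2)
    r6 = _ring_at(c, lig_res, (0, 0, 0), (0, 0, 1))
    r5 = _ring_at(c, lig_res, (2.2, 0, 0), (0, 0, 1))
    key = (lig_res.key, "base")
    r6.system_key = key
    r5.system_key = key
    lig = FeatureSet()
    lig.rings.extend([r6, r5])
    rec = FeatureSet()
    rec.rings.append(_ring_at(c, make_residue("PHE", "amino_acid", "A", 438),
                              (0.3, 0, 3.8), (0, 0, 1)))
    found = detect_pistacking(lig, rec, CFG)
    assert len(found) == 1
    assert found[0].lig_ring is r6  # smaller lateral offset wins


def test_detector_ordering_is_deterministic():
    rng = np.random.default_rng(3)
    lig, rec = microgeo.gen_hbond(rng)
    a = [(hb.donor.serial, hb.acceptor.serial)
         for hb in detect_hbonds(lig, rec, CFG)]
    b = [(hb.donor.serial, hb.acceptor.serial)
         for hb in detect_hbonds(lig, rec, CFG)]
    assert a == b


# ---------------------------------------------------------------------------
# properties

@pytest.mark.parametrize("detector", DETECTORS)
def test_detector_matches_brute_force_oracle(detector):
    """Spot-check equivalence on 25 random micro-geometries per detector
    (the full 200-trial sweep runs in the acceptance tests)."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        assert compare_one(detector, rng, CFG)


def test_raising_distance_thresholds_never_removes_interactions():
    rng = np.random.default_rng(5)
    for _ in range(20):
        lig, rec = microgeo.gen_hydrophobic(rng)
        loose = CFG.replace(hydroph_dist_max=CFG.hydroph_dist_max + 1.0)
        tight_pairs = {(c.lig_atom.serial, c.rec_atom.serial)
                       for c in detect_hydrophobic(lig, rec, CFG,
                                                   refine=False)}
        loose_pairs = {(c.lig_atom.serial, c.rec_atom.serial)
                       for c in detect_hydrophobic(lig, rec, loose,
                                                   refine=False)}
        assert tight_pairs <= loose_pairs


def test_lowering_hbond_angle_minimum_never_removes_bonds():
    rng = np.random.default_rng(6)
    for _ in range(20):
        lig, rec = microgeo.gen_hbond(rng)
        lower = CFG.replace(hbond_don_angle_min=80.0)
        strict = {(hb.donor.serial, hb.acceptor.serial)
                  for hb in detect_hbonds(lig, rec, CFG)}
        loose = {(hb.donor.serial, hb.acceptor.serial)
                 for hb in detect_hbonds(lig, rec, lower)}
        assert strict <= loose


def test_swapping_sides_preserves_geometric_pairs():
    """Ligand/receptor label swap: the same geometric pairs are found with
    roles exchanged; donor/acceptor roles stay with the atoms."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        lig, rec = microgeo.gen_hbond(rng)
        fwd = {(hb.donor.serial, hb.acceptor.serial)
               for hb in detect_hbonds(lig, rec, CFG)}
        rev = {(hb.donor.serial, hb.acceptor.serial)
               for hb in detect_hbonds(rec, lig, CFG)}
        assert fwd == rev
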