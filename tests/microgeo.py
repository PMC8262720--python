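"""Seeded random micro-geometries (<= 60 atoms) for detector/oracle
equivalence checks.

Each generator builds feature sets directly (atoms with residue parents,
rings, charges, ...) so a detector run and a brute-force oracle run see
exactly the same inputs.
"""

import math

import numpy as np

from nciprof.features import (AromaticRing, ChargedCenter, FeatureSet,
                              HalogenDonor, HBondAcceptor, HBondDonor,
                              HydrophobicAtom, MetalAtom, WaterOxygen)
from nciprof.structure import Atom, Residue

BOX = 8.0


class Counter:
    def __init__(self):
        self.n = 0

    def next(self):
        self.n += 1
        return self.n


def make_residue(name="LIG", kind="other_hetero", chain="L", seq=1):
    res = Residue(name=name, seq_number=seq, insertion_code="",
                  chain_id=chain)
    res.kind = kind
    return res


def make_atom(counter, res, element="C", name=None, coords=(0, 0, 0)):
    atom = Atom(serial=counter.next(), name=name or element,
                element=element, coords=np.asarray(coords, float),
                is_hetero=(res.kind == "other_hetero"), parent=res)
    res.atoms.append(atom)
    return atom


def _rand_point(rng):
    return rng.uniform(0, BOX, 3)


def _rand_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rec_residues(rng, n=3):
    return [make_residue("ALA", "amino_acid", "A", i + 1) for i in range(n)]


def gen_hydrophobic(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()
    for _ in range(int(rng.integers(1, 9))):
        lig.hydrophobics.append(
            HydrophobicAtom(make_atom(c, lig_res, coords=_rand_point(rng))))
    for i in range(int(rng.integers(1, 9))):
        res = recs[i % len(recs)]
        rec.hydrophobics.append(
            HydrophobicAtom(make_atom(c, res, coords=_rand_point(rng))))
    return lig, rec


def gen_hbond(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()

    def add_donor(fs, res):
        d = make_atom(c, res, element="N", coords=_rand_point(rng))
        h = make_atom(c, res, element="H",
                      coords=d.coords + 1.0 * _rand_unit(rng))
        fs.donors.append(HBondDonor(d, [h]))

    def add_acceptor(fs, res):
        a = make_atom(c, res, element="O", coords=_rand_point(rng))
        fs.acceptors.append(HBondAcceptor(a))

    for _ in range(int(rng.integers(1, 5))):
        add_donor(lig, lig_res)
    for _ in range(int(rng.integers(1, 4))):
        add_acceptor(lig, lig_res)
    for i in range(int(rng.integers(1, 5))):
        add_donor(rec, recs[i % 3])
    for i in range(int(rng.integers(1, 4))):
        add_acceptor(rec, recs[i % 3])
    return lig, rec


def gen_water_bridge(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    wres = [make_residue("HOH", "water", "W", i + 1) for i in range(3)]
    lig = FeatureSet()
    rec = FeatureSet()
    waters = []

    def add_polar(fs, res):
        a = make_atom(c, res, element="O", coords=_rand_point(rng))
        role = int(rng.integers(0, 3))  # 0 donor, 1 acceptor, 2 both
        if role in (0, 2):
            h = make_atom(c, res, element="H",
                          coords=a.coords + 1.0 * _rand_unit(rng))
            fs.donors.append(HBondDonor(a, [h]))
        if role in (1, 2):
            fs.acceptors.append(HBondAcceptor(a))
        return a, role in (0, 2), role in (1, 2)

    lig_polar = [add_polar(lig, lig_res)
                 for _ in range(int(rng.integers(1, 4)))]
    rec_polar = [add_polar(rec, recs[i % 3])
                 for i in range(int(rng.integers(1, 4)))]
    for i in range(int(rng.integers(1, 4))):
        w = make_atom(c, wres[i], element="O", coords=_rand_point(rng))
        waters.append(WaterOxygen(w))
    return lig, rec, waters, lig_polar, rec_polar


def gen_salt_bridge(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()

    def add_charge(fs, res, ligside):
        center = _rand_point(rng)
        atoms = [make_atom(c, res, element="O",
                           coords=center + rng.normal(0, 0.5, 3))
                 for _ in range(int(rng.integers(1, 4)))]
        sign = "positive" if rng.random() < 0.5 else "negative"
        ch = ChargedCenter(atoms, sign, "group")
        (fs.pos_charges if sign == "positive" else fs.neg_charges).append(ch)
        return ch

    lig_ch = [add_charge(lig, lig_res, True)
              for _ in range(int(rng.integers(1, 4)))]
    rec_ch = [add_charge(rec, recs[i % 3], False)
              for i in range(int(rng.integers(1, 4)))]
    return lig, rec, lig_ch, rec_ch


def _random_ring(rng, c, res, n_atoms=6, radius=1.39):
    center = _rand_point(rng)
    normal = _rand_unit(rng)
    u = np.cross(normal, [0, 0, 1.0]
                 if abs(normal[2]) < 0.9 else [1.0, 0, 0])
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = []
    for k in range(n_atoms):
        a = 2 * math.pi * k / n_atoms
        atoms.append(make_atom(
            c, res, coords=center + radius * (math.cos(a) * u
                                              + math.sin(a) * v)))
    return AromaticRing(atoms)


def gen_pistack(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()
    for _ in range(int(rng.integers(1, 4))):
        lig.rings.append(_random_ring(rng, c, lig_res,
                                      int(rng.choice([5, 6]))))
    for i in range(int(rng.integers(1, 4))):
        rec.rings.append(_random_ring(rng, c, recs[i % 3],
                                      int(rng.choice([5, 6]))))
    return lig, rec


def gen_pication(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()
    for _ in range(int(rng.integers(1, 4))):
        lig.rings.append(_random_ring(rng, c, lig_res))
    for i in range(int(rng.integers(1, 4))):
        res = recs[i % 3]
        center = _rand_point(rng)
        atoms = [make_atom(c, res, element="N",
                           coords=center + rng.normal(0, 0.6, 3))
                 for _ in range(int(rng.integers(1, 5)))]
        label = "guanidinium" if rng.random() < 0.5 else "ammonium"
        rec.pos_charges.append(ChargedCenter(atoms, "positive", label))
    return lig, rec


def gen_halogen(rng):
    c = Counter()
    lig_res = make_residue()
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()
    adjacency = {}
    for _ in range(int(rng.integers(1, 4))):
        x = make_atom(c, lig_res, element="CL", name="CL1",
                      coords=_rand_point(rng))
        cc = make_atom(c, lig_res, element="C",
                       coords=x.coords + 1.74 * _rand_unit(rng))
        lig.halogen_donors.append(HalogenDonor(x, cc))
    acc_pairs = []
    for i in range(int(rng.integers(1, 4))):
        res = recs[i % 3]
        a = make_atom(c, res, element="O", coords=_rand_point(rng))
        y = make_atom(c, res, element="C",
                      coords=a.coords + 1.23 * _rand_unit(rng))
        adjacency[a] = {y}
        rec.acceptors.append(HBondAcceptor(a))
        acc_pairs.append((a, y))
    return lig, rec, adjacency, acc_pairs


def gen_metal(rng):
    c = Counter()
    lig_res = make_residue("MG", "metal_ion")
    recs = _rec_residues(rng)
    lig = FeatureSet()
    rec = FeatureSet()
    for _ in range(int(rng.integers(1, 3))):
        lig.metals.append(MetalAtom(
            make_atom(c, lig_res, element="MG", coords=_rand_point(rng))))
    for i in range(int(rng.integers(1, 9))):
        res = recs[i % 3]
        a = make_atom(c, res, element="O",
                      coords=lig.metals[0].atom.coords
                      + rng.uniform(1.8, 4.0) * _rand_unit(rng))
        rec.acceptors.append(HBondAcceptor(a))
    return lig, rec
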