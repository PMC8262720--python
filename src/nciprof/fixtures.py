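"""Synthetic PDB fixtures with planted interactions and ground-truth manifests.

Each planted interaction places a minimal chemical group pair (formamide- or
methanol-like donors, carbonyl acceptors, benzene/pyrazine rings, a guanine
base, phosphates, waters, metals with coordination spheres) at a requested
geometry. The generator writes a syntactically valid PDB file and a
:class:`FixtureManifest` whose expected interactions are computed from the
file's own 3-decimal coordinates by applying the inclusive geometric rules
directly - so the manifest is exact ground truth for the written file, even
at thresholds.

All fixtures are synthetic constructions, not excerpts of deposited
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ThresholdConfig
from .features import _AROMATIC_BOND_MAX, _DOUBLE_BOND_CO
from .geometry import angle_deg, distance, fit_plane, plane_angle_deg, ring_offset

__all__ = ["FixtureManifest", "FixtureAtom", "generate_fixture",
           "standard_suite", "multimodel_fixture", "evaluate_fixture",
           "nucleic_complex_fixture"]


class FixtureError(ValueError):
    """Geometrically infeasible fixture specification."""


@dataclass(eq=False)
class FixtureAtom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    resname: str
    chain: str
    seq: int
    hetero: bool


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture file."""

    name: str = ""
    #: expected interaction records: type -> list of dicts (serials + geometry)
    expected: dict = field(default_factory=dict)
    #: ATOM/HETATM count per model
    atom_counts: list = field(default_factory=list)
    #: analysis-mode flags the fixture must be profiled with
    mode_flags: dict = field(default_factory=dict)
    #: threshold overrides the fixture must be profiled with (normally none)
    config_overrides: dict = field(default_factory=dict)

    def add(self, itype: str, record: dict):
        self.expected.setdefault(itype, []).append(record)

    def count(self, itype: str) -> int:
        return len(self.expected.get(itype, []))

    def to_tsv(self) -> str:
        """Serialise expected records as tab-separated text."""
        lines = ["# fixture manifest\tname=" + self.name]
        for itype in sorted(self.expected):
            for rec in self.expected[itype]:
                fields = [f"{k}={v}" for k, v in sorted(rec.items())]
                lines.append("\t".join([itype] + fields))
        return "\n".join(lines) + "\n"


class _Builder:
    def __init__(self):
        self.atoms: list = []
        self._serial = 0

    def add(self, name, element, coords, resname, chain, seq, hetero):
        self._serial += 1
        atom = FixtureAtom(self._serial, name, element,
                           np.asarray(coords, float), resname, chain, seq,
                           hetero)
        self.atoms.append(atom)
        return atom

    def quantize(self):
        for a in self.atoms:
            a.coords = np.round(a.coords, 3)

    def jitter(self, rng, sigma):
        for a in self.atoms:
            a.coords = a.coords + np.clip(
                rng.normal(0.0, sigma, 3), -0.05, 0.05)

    def check_clashes(self):
        for i, a in enumerate(self.atoms):
            for b in self.atoms[i + 1:]:
                if np.linalg.norm(a.coords - b.coords) < 0.5:
                    raise FixtureError(
                        f"overlapping atoms {a.serial}/{b.serial} in fixture")

    def to_pdb(self) -> str:
        lines = []
        for a in self.atoms:
            rec = "HETATM" if a.hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 or len(a.element) == 2 \
                else f" {a.name}"
            lines.append(
                f"{rec}{a.serial:5d} {name:<4s} {a.resname:<3s} {a.chain:1s}"
                f"{a.seq:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}"
                f"{a.coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}")
        lines.append("END")
        return "\n".join(lines) + "\n"


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _hexagon(side=1.39):
    """Regular hexagon in the xy-plane, centred on the origin."""
    return [np.array([side * math.cos(math.radians(60 * k + 90)),
                      side * math.sin(math.radians(60 * k + 90)), 0.0])
            for k in range(6)]


# ---------------------------------------------------------------------------
# group builders (receptor side is chain A protein; ligand side chain L)

def _gly_acceptor(b, o_pos, away, chain, seq):
    """GLY whose carbonyl O sits at ``o_pos``; the rest extends along ``away``."""
    away = _unit(away)
    perp = _unit(np.cross(away, _Z if abs(away[2]) < 0.9 else _Y))
    c = o_pos + 1.23 * away
    ca = c + 1.52 * _unit(away + 0.8 * perp)
    n = ca + 1.46 * _unit(away - 0.4 * perp)
    b.add("N", "N", n, "GLY", chain, seq, False)
    b.add("CA", "C", ca, "GLY", chain, seq, False)
    cc = b.add("C", "C", c, "GLY", chain, seq, False)
    oo = b.add("O", "O", o_pos, "GLY", chain, seq, False)
    return oo, cc


def _ala_contact(b, cb_pos, away, chain, seq):
    """ALA whose CB sits at ``cb_pos``; backbone extends along ``away``."""
    away = _unit(away)
    perp = _unit(np.cross(away, _Z if abs(away[2]) < 0.9 else _Y))
    ca = cb_pos + 1.53 * away
    n = ca + 1.46 * _unit(away + 0.9 * perp)
    c = ca + 1.52 * _unit(away - 0.9 * perp)
    o = c + 1.23 * away
    b.add("N", "N", n, "ALA", chain, seq, False)
    b.add("CA", "C", ca, "ALA", chain, seq, False)
    b.add("C", "C", c, "ALA", chain, seq, False)
    b.add("O", "O", o, "ALA", chain, seq, False)
    return b.add("CB", "C", cb_pos, "ALA", chain, seq, False)


def _lys_cation(b, nz_pos, away, chain, seq):
    """LYS whose ammonium NZ sits at ``nz_pos``, side chain along ``away``."""
    away = _unit(away)
    perp = _unit(np.cross(away, _Z if abs(away[2]) < 0.9 else _Y))
    ce = nz_pos + 1.49 * away
    cd = ce + 1.53 * _unit(away + 0.4 * perp)
    cg = cd + 1.53 * _unit(away - 0.4 * perp)
    cb = cg + 1.53 * _unit(away + 0.4 * perp)
    ca = cb + 1.53 * _unit(away - 0.4 * perp)
    n = ca + 1.46 * perp
    c = ca + 1.52 * _unit(away + 0.8 * perp)
    o = c + 1.23 * away
    b.add("N", "N", n, "LYS", chain, seq, False)
    b.add("CA", "C", ca, "LYS", chain, seq, False)
    b.add("C", "C", c, "LYS", chain, seq, False)
    b.add("O", "O", o, "LYS", chain, seq, False)
    b.add("CB", "C", cb, "LYS", chain, seq, False)
    b.add("CG", "C", cg, "LYS", chain, seq, False)
    b.add("CD", "C", cd, "LYS", chain, seq, False)
    b.add("CE", "C", ce, "LYS", chain, seq, False)
    return b.add("NZ", "N", nz_pos, "LYS", chain, seq, False)


def _arg_guanidinium(b, cz_pos, plane_u, plane_v, away, chain, seq):
    """ARG guanidinium: CZ at ``cz_pos``, NH1/NH2/NE in the (u, v) plane."""
    away = _unit(away)
    ne = cz_pos + 1.33 * _unit(-0.5 * plane_u + math.sqrt(3) / 2 * plane_v)
    nh1 = cz_pos + 1.33 * plane_u
    nh2 = cz_pos + 1.33 * _unit(-0.5 * plane_u - math.sqrt(3) / 2 * plane_v)
    cd = ne + 1.46 * away
    cg = cd + 1.53 * _unit(away + 0.4 * plane_u)
    cb = cg + 1.53 * _unit(away - 0.4 * plane_u)
    ca = cb + 1.53 * _unit(away + 0.4 * plane_u)
    n = ca + 1.46 * plane_v
    c = ca + 1.52 * _unit(away - 0.6 * plane_v)
    o = c + 1.23 * away
    b.add("N", "N", n, "ARG", chain, seq, False)
    b.add("CA", "C", ca, "ARG", chain, seq, False)
    b.add("C", "C", c, "ARG", chain, seq, False)
    b.add("O", "O", o, "ARG", chain, seq, False)
    b.add("CB", "C", cb, "ARG", chain, seq, False)
    b.add("CG", "C", cg, "ARG", chain, seq, False)
    b.add("CD", "C", cd, "ARG", chain, seq, False)
    ne_a = b.add("NE", "N", ne, "ARG", chain, seq, False)
    cz_a = b.add("CZ", "C", cz_pos, "ARG", chain, seq, False)
    nh1_a = b.add("NH1", "N", nh1, "ARG", chain, seq, False)
    nh2_a = b.add("NH2", "N", nh2, "ARG", chain, seq, False)
    return cz_a, nh1_a, nh2_a, ne_a


def _phe_ring(b, center, normal, chain, seq, ref_in_plane=None):
    """PHE with its six-membered ring centred at ``center`` with ``normal``."""
    normal = _unit(normal)
    u = _unit(np.cross(normal, _Z if abs(normal[2]) < 0.9 else _X))
    v = np.cross(normal, u)
    if ref_in_plane is not None:
        u = _unit(ref_in_plane - np.dot(ref_in_plane, normal) * normal)
        v = np.cross(normal, u)
    pts = [center + 1.39 * (math.cos(math.radians(60 * k)) * u +
                            math.sin(math.radians(60 * k)) * v)
           for k in range(6)]
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    ring = [b.add(nm, "C", p, "PHE", chain, seq, False)
            for nm, p in zip(names, pts)]
    cb = pts[0] + 1.51 * _unit(pts[0] - center)
    ca = cb + 1.53 * _unit(pts[0] - center)
    n = ca + 1.46 * _unit(np.asarray(_unit(pts[0] - center)) + 0.9 * normal)
    c = ca + 1.52 * _unit(np.asarray(_unit(pts[0] - center)) - 0.9 * normal)
    o = c + 1.23 * _unit(pts[0] - center)
    b.add("N", "N", n, "PHE", chain, seq, False)
    b.add("CA", "C", ca, "PHE", chain, seq, False)
    b.add("C", "C", c, "PHE", chain, seq, False)
    b.add("O", "O", o, "PHE", chain, seq, False)
    b.add("CB", "C", cb, "PHE", chain, seq, False)
    return ring


def _pyrazine(b, center, normal, chain, seq, resname="LIG", ref_in_plane=None):
    """Pyrazine ligand ring (N1, C2, C3, N4, C5, C6): aromatic, acceptors
    only, contributes no hydrophobic carbons and no donors."""
    normal = _unit(normal)
    u = _unit(np.cross(normal, _Z if abs(normal[2]) < 0.9 else _X))
    if ref_in_plane is not None:
        u = _unit(ref_in_plane - np.dot(ref_in_plane, normal) * normal)
    v = np.cross(normal, u)
    pts = [center + 1.35 * (math.cos(math.radians(60 * k)) * u +
                            math.sin(math.radians(60 * k)) * v)
           for k in range(6)]
    names = ["N1", "C2", "C3", "N4", "C5", "C6"]
    elements = ["N", "C", "C", "N", "C", "C"]
    return [b.add(nm, el, p, resname, chain, seq, True)
            for nm, el, p in zip(names, elements, pts)]


def _benzene(b, center, normal, chain, seq, resname="LIG", ref_in_plane=None):
    normal = _unit(normal)
    u = _unit(np.cross(normal, _Z if abs(normal[2]) < 0.9 else _X))
    if ref_in_plane is not None:
        u = _unit(ref_in_plane - np.dot(ref_in_plane, normal) * normal)
    v = np.cross(normal, u)
    pts = [center + 1.39 * (math.cos(math.radians(60 * k)) * u +
                            math.sin(math.radians(60 * k)) * v)
           for k in range(6)]
    return [b.add(f"C{k + 1}", "C", p, resname, chain, seq, True)
            for k, p in enumerate(pts)]


def _water(b, o_pos, chain, seq):
    return b.add("O", "O", o_pos, "HOH", chain, seq, True)


def _uracil(b, origin, chain, seq, resname="U", hetero=False, with_c7=False):
    """Uracil (or thymine, with ``with_c7``) base: hexagon + O2/O4 + C1'."""
    hexpts = [p + origin for p in _hexagon(1.37)]
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    elems = ["N", "C", "N", "C", "C", "C"]
    atoms = {}
    for nm, el, p in zip(names, elems, hexpts):
        atoms[nm] = b.add(nm, el, p, resname, chain, seq, hetero)

    def _subst(nm, el, on, nb1, nb2, ln):
        d = _unit(2 * atoms[on].coords - atoms[nb1].coords
                  - atoms[nb2].coords)
        atoms[nm] = b.add(nm, el, atoms[on].coords + ln * d,
                          resname, chain, seq, hetero)

    _subst("O2", "O", "C2", "N1", "N3", 1.23)
    _subst("O4", "O", "C4", "N3", "C5", 1.23)
    _subst("C1'", "C", "N1", "C2", "C6", 1.47)
    if with_c7:
        _subst("C7", "C", "C5", "C4", "C6", 1.50)
    return atoms


def _guanine(b, origin, chain, seq, resname="G", hetero=False,
             with_n1_h=False, with_phosphate=False):
    """Guanine base in the z=0 plane (fused 6+5 ring, O6/N2 substituents,
    C1' stub). Returns a dict of the created atoms by canonical name."""
    hexpts = [p + origin for p in _hexagon(1.37)]
    hexnames = ["N1", "C2", "N3", "C4", "C5", "C6"]
    hexelem = ["N", "C", "N", "C", "C", "C"]
    atoms = {}
    # fuse the pentagon on the C4-C5 edge, on the far side of the hexagon
    p4, p5 = hexpts[3], hexpts[4]
    edge_mid = (p4 + p5) / 2
    out_dir = _unit(edge_mid - origin)
    s = float(np.linalg.norm(p5 - p4))
    apothem = s / (2 * math.tan(math.radians(36)))
    radius = s / (2 * math.sin(math.radians(36)))
    pcenter = edge_mid + apothem * out_dir
    ang4 = math.atan2(p4[1] - pcenter[1], p4[0] - pcenter[0])
    ang5 = math.atan2(p5[1] - pcenter[1], p5[0] - pcenter[0])
    # walk the pentagon from C4 away from C5: N9, C8, N7
    step = math.radians(72)
    diff = (ang5 - ang4) % (2 * math.pi)
    sign = 1.0 if diff > math.pi else -1.0  # direction from C4 away from C5
    pent = {}
    for i, nm in enumerate(("N9", "C8", "N7"), start=1):
        a = ang4 + sign * step * i
        pent[nm] = pcenter + radius * np.array(
            [math.cos(a), math.sin(a), 0.0])
    for nm, el, p in zip(hexnames, hexelem, hexpts):
        atoms[nm] = b.add(nm, el, p, resname, chain, seq, hetero)
    for nm in ("N7", "C8", "N9"):
        atoms[nm] = b.add(nm, "N" if nm.startswith("N") else "C",
                          pent[nm], resname, chain, seq, hetero)

    def _subst(name, element, on, nb1, nb2, length):
        d = _unit(2 * atoms[on].coords - atoms[nb1].coords - atoms[nb2].coords)
        atoms[name] = b.add(name, element, atoms[on].coords + length * d,
                            resname, chain, seq, hetero)

    _subst("O6", "O", "C6", "N1", "C5", 1.23)
    _subst("N2", "N", "C2", "N1", "N3", 1.34)
    _subst("C1'", "C", "N9", "C8", "C4", 1.47)
    if with_n1_h:
        d = _unit(2 * atoms["N1"].coords - atoms["C2"].coords
                  - atoms["C6"].coords)
        atoms["H1"] = b.add("H1", "H", atoms["N1"].coords + 1.01 * d,
                            resname, chain, seq, hetero)
    if with_phosphate:
        c1 = atoms["C1'"].coords
        d = _unit(c1 - atoms["N9"].coords)
        p = c1 + 2.6 * d + np.array([0.0, 0.0, 1.0])
        atoms["P"] = b.add("P", "P", p, resname, chain, seq, hetero)
        atoms["OP1"] = b.add("OP1", "O", p + 1.48 * _unit(d + _Z),
                             resname, chain, seq, hetero)
        atoms["OP2"] = b.add("OP2", "O", p + 1.48 * _unit(d - _Z),
                             resname, chain, seq, hetero)
        atoms["O5'"] = b.add("O5'", "O", p + 1.59 * _unit(
            np.cross(d, _Z) + 0.3 * d), resname, chain, seq, hetero)
    return atoms


# ---------------------------------------------------------------------------
# expectation helpers: apply the inclusive rules to the final coordinates

def _ring_still_aromatic(ring, cfg):
    """Under jitter a generated ring can leave the engine's aromaticity
    definition (bond length / planarity); the manifest must agree."""
    n = len(ring)
    for i in range(n):
        if distance(ring[i].coords, ring[(i + 1) % n].coords) \
                > _AROMATIC_BOND_MAX:
            return False
    _, _, rmsd = fit_plane([a.coords for a in ring])
    return rmsd <= cfg.ring_planarity_max

def _expect_hydrophobic(man, cfg, lig_atom, rec_atom):
    d = distance(lig_atom.coords, rec_atom.coords)
    if d <= cfg.hydroph_dist_max:
        man.add("hydrophobic", {"lig_serial": lig_atom.serial,
                                "rec_serial": rec_atom.serial, "dist": d})


def _expect_hbond(man, cfg, donor, hydrogen, acceptor):
    d_da = distance(donor.coords, acceptor.coords)
    if d_da > cfg.hbond_dist_max:
        return
    ang = angle_deg(donor.coords, hydrogen.coords, acceptor.coords)
    if ang >= cfg.hbond_don_angle_min:
        man.add("hbond", {"donor_serial": donor.serial,
                          "acceptor_serial": acceptor.serial,
                          "dist_da": d_da, "angle": ang})


def _expect_water_bridge(man, cfg, donor, acceptor, water):
    d_dw = distance(donor.coords, water.coords)
    d_aw = distance(acceptor.coords, water.coords)
    omega = angle_deg(donor.coords, water.coords, acceptor.coords)
    if (cfg.water_bridge_mindist <= d_dw <= cfg.water_bridge_maxdist and
            cfg.water_bridge_mindist <= d_aw <= cfg.water_bridge_maxdist and
            cfg.water_bridge_omega_min <= omega <= cfg.water_bridge_omega_max):
        man.add("water_bridge", {"donor_serial": donor.serial,
                                 "acceptor_serial": acceptor.serial,
                                 "water_serial": water.serial,
                                 "dist_donor_water": d_dw,
                                 "dist_acceptor_water": d_aw, "omega": omega})


def _expect_salt_bridge(man, cfg, pos_atoms, neg_atoms):
    pc = np.mean([a.coords for a in pos_atoms], axis=0)
    nc = np.mean([a.coords for a in neg_atoms], axis=0)
    d = distance(pc, nc)
    if d <= cfg.saltbridge_dist_max:
        man.add("salt_bridge", {
            "pos_serials": frozenset(a.serial for a in pos_atoms),
            "neg_serials": frozenset(a.serial for a in neg_atoms),
            "dist": d})


def _expect_pistack(man, cfg, lig_ring, rec_ring):
    c1, n1, _ = fit_plane([a.coords for a in lig_ring])
    c2, n2, _ = fit_plane([a.coords for a in rec_ring])
    d = distance(c1, c2)
    if d > cfg.pistack_dist_max:
        return
    ang = plane_angle_deg(n1, n2)
    if ang <= cfg.pistack_ang_dev:
        stype = "P"
    elif ang >= 90.0 - cfg.pistack_ang_dev:
        stype = "T"
    else:
        return
    off = min(ring_offset(c1, n1, c2), ring_offset(c2, n2, c1))
    if off <= cfg.pistack_offset_max:
        man.add("pistack", {
            "lig_serials": frozenset(a.serial for a in lig_ring),
            "rec_serials": frozenset(a.serial for a in rec_ring),
            "dist": d, "stack_type": stype, "angle": ang, "offset": off})


def _expect_pication(man, cfg, ring, charge_atoms, guanidinium):
    c1, n1, _ = fit_plane([a.coords for a in ring])
    cc = np.mean([a.coords for a in charge_atoms], axis=0)
    d = distance(c1, cc)
    if d > cfg.pication_dist_max:
        return
    if guanidinium:
        from .geometry import vector_angle_deg
        ang = vector_angle_deg(n1, cc - c1)
        ang = min(ang, 180.0 - ang)
        if ang > cfg.pication_face_angle_max:
            return
    man.add("pication", {
        "ring_serials": frozenset(a.serial for a in ring),
        "charge_serials": frozenset(a.serial for a in charge_atoms),
        "dist": d})


def _expect_halogen(man, cfg, halogen, carbon, acceptor, y_atom):
    d = distance(halogen.coords, acceptor.coords)
    if d > cfg.halogen_dist_max:
        return
    don = angle_deg(carbon.coords, halogen.coords, acceptor.coords)
    acc = angle_deg(y_atom.coords, acceptor.coords, halogen.coords)
    if (abs(don - cfg.halogen_don_angle) <= cfg.halogen_don_angle_dev and
            abs(acc - cfg.halogen_acc_angle) <= cfg.halogen_acc_angle_dev):
        man.add("halogen", {"halogen_serial": halogen.serial,
                            "acceptor_serial": acceptor.serial,
                            "dist": d, "don_angle": don, "acc_angle": acc})


def _expect_metal(man, cfg, metal, targets, geometry_label):
    within = [(t, distance(metal.coords, t.coords)) for t in targets]
    within = [(t, d) for t, d in within if d <= cfg.metal_dist_max]
    for t, d in within:
        man.add("metal", {"metal_serial": metal.serial,
                          "target_serial": t.serial, "dist": d,
                          "geometry": geometry_label if len(within) > 1
                          else "other/underdetermined",
                          "coordination_number": len(within)})


# ---------------------------------------------------------------------------
# planted-interaction builders

def _plant_hydrophobic(b, man, cfg, origin, dist):
    c1 = b.add("C1", "C", origin, "LIG", "L", 1, True)
    b.add("C2", "C", origin - 1.53 * _X, "LIG", "L", 1, True)
    cb = _ala_contact(b, origin + dist * _X, _X, "A", 1)
    return lambda: _expect_hydrophobic(man, cfg, c1, cb)


def _plant_hydrophobic_cluster(b, man, cfg, origin, dists=(3.5, 3.7, 3.9)):
    """Several ligand carbons around one receptor carbon: the clustering
    rule must reduce them to the single closest contact."""
    cb_pos = origin
    cb = _ala_contact(b, cb_pos, _X, "A", 1)
    lig = []
    dirs = [-_X, _unit(-_X + 0.35 * _Y), _unit(-_X - 0.35 * _Y)]
    for i, (d, u) in enumerate(zip(dists, dirs), start=1):
        lig.append(b.add(f"C{i}", "C", cb_pos + d * u, "LIG", "L", 1, True))

    def expect():
        pairs = sorted(((distance(a.coords, cb.coords), a) for a in lig),
                       key=lambda t: t[0])
        d, a = pairs[0]
        if d <= cfg.hydroph_dist_max:
            man.add("hydrophobic", {"lig_serial": a.serial,
                                    "rec_serial": cb.serial, "dist": d})
    return expect


def _plant_hbond(b, man, cfg, origin, dist, angle):
    """Methanol donor (explicit H, so the angle is controlled) against a
    GLY carbonyl acceptor."""
    o = b.add("O1", "O", origin, "LIG", "L", 1, True)
    c1 = b.add("C1", "C", origin - 1.43 * _X, "LIG", "L", 1, True)
    acc_pos = origin + dist * _X
    # choose the O-H direction so that the D-H...A angle equals ``angle``
    theta = math.radians(180.0 - angle)

    def h_for(phi):
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        return origin + 0.96 * u

    # bisection on the in-plane H direction angle phi
    lo, hi = 0.0, math.radians(179.0)

    def ang_at(phi):
        h = h_for(phi)
        return angle_deg(origin, h, acc_pos)

    for _ in range(60):
        mid = (lo + hi) / 2
        if ang_at(mid) > angle:
            lo = mid
        else:
            hi = mid
    h = b.add("H1", "H", h_for((lo + hi) / 2), "LIG", "L", 1, True)
    del theta
    acc, _c = _gly_acceptor(b, acc_pos, _X, "A", 1)

    def expect():
        # under jitter the C-O bond may shrink into carbonyl range, where
        # generic perception no longer sees a hydroxyl donor
        if distance(c1.coords, o.coords) > _DOUBLE_BOND_CO:
            _expect_hbond(man, cfg, o, h, acc)
    return expect


def _plant_water_bridge(b, man, cfg, origin, leg1, leg2, omega,
                        acc_offset=None):
    """``acc_offset`` overrides the acceptor-water vector with exact
    components (e.g. the Pythagorean (0.9, 4.0) for an exact 4.1 A leg that
    survives 3-decimal coordinate quantisation)."""
    o = b.add("O1", "O", origin, "LIG", "L", 1, True)
    b.add("C1", "C", origin - 1.43 * _X, "LIG", "L", 1, True)
    h = b.add("H1", "H", origin + 0.96 * _X, "LIG", "L", 1, True)
    w_pos = origin + leg1 * _X
    if acc_offset is not None:
        acc_pos = w_pos + np.array([acc_offset[0], acc_offset[1], 0.0])
    else:
        rad = math.radians(omega)
        acc_pos = w_pos + leg2 * (math.cos(rad) * (-_X) + math.sin(rad) * _Y)
    w = _water(b, w_pos, "W", 1)
    acc, _c = _gly_acceptor(b, acc_pos, _unit(acc_pos - w_pos), "A", 1)

    def expect():
        # a direct hydrogen bond would suppress the bridge
        d_direct = distance(o.coords, acc.coords)
        if d_direct <= cfg.hbond_dist_max and \
                angle_deg(o.coords, h.coords, acc.coords) >= cfg.hbond_don_angle_min:
            _expect_hbond(man, cfg, o, h, acc)
            return
        _expect_water_bridge(man, cfg, o, acc, w)
    return expect


def _plant_salt_bridge(b, man, cfg, origin, dist):
    """Acetate ligand (carboxylate) against a LYS ammonium; the ionic pair
    subsumes any member hydrogen bonds."""
    c2 = origin
    # O-C-O angle ~123 deg so the two oxygens sit a non-bonded 2.2 A apart
    o1 = c2 + 1.25 * _unit(_X + 1.84 * _Y)
    o2 = c2 + 1.25 * _unit(_X - 1.84 * _Y)
    b.add("C1", "C", c2 - 1.52 * _X, "LIG", "L", 1, True)
    b.add("C2", "C", c2, "LIG", "L", 1, True)
    a_o1 = b.add("O1", "O", o1, "LIG", "L", 1, True)
    a_o2 = b.add("O2", "O", o2, "LIG", "L", 1, True)
    neg_centroid = (o1 + o2) / 2
    nz = _lys_cation(b, neg_centroid + dist * _X, _X, "A", 1)
    return lambda: _expect_salt_bridge(man, cfg, [nz], [a_o1, a_o2])


def _plant_pistack(b, man, cfg, origin, dist, angle, offset, t_shaped=False):
    lig_ring = _pyrazine(b, origin, _Z, "L", 1)
    h = math.sqrt(max(dist ** 2 - offset ** 2, 0.0))
    center2 = origin + offset * _X + h * _Z
    if t_shaped:
        normal2 = _X
    else:
        rad = math.radians(angle)
        normal2 = math.cos(rad) * _Z + math.sin(rad) * _X
    rec_ring = _phe_ring(b, center2, normal2, "A", 1, ref_in_plane=_Y)

    def expect():
        # the receptor PHE ring comes from a template; the ligand ring must
        # still pass generic aromatic perception after jitter
        if _ring_still_aromatic(lig_ring, cfg):
            _expect_pistack(man, cfg, lig_ring, rec_ring)
    return expect


def _plant_pication(b, man, cfg, origin, dist, in_plane=False):
    ring = _benzene(b, origin, _Z, "L", 1)
    if in_plane:
        cz = origin + dist * _X
        away = _X
    else:
        cz = origin + dist * _Z
        away = _Z
    czc = cz  # the charge centroid is CZ+NH1+NH2+NE mean; construct around it
    cz_a, nh1, nh2, ne = _arg_guanidinium(
        b, czc, _Y if not in_plane else _Z, _X if not in_plane else _Y,
        away, "A", 1)
    charge_atoms = [cz_a, nh1, nh2, ne]

    def expect():
        if _ring_still_aromatic(ring, cfg):
            _expect_pication(man, cfg, ring, charge_atoms, guanidinium=True)
    return expect


def _plant_halogen(b, man, cfg, origin, dist, don_angle, acc_angle,
                   element="CL", acc_offset=None):
    """Halobenzene sigma-hole donor vs a GLY carbonyl acceptor.

    ``acc_offset`` places the acceptor at an exact in-plane offset from the
    halogen (overriding ``dist``/``don_angle``), so at-threshold distances
    survive 3-decimal quantisation.
    """
    cx = 1.74 if element == "CL" else 1.90
    c1_pos = origin - cx * _X
    # ring centre behind C1 so only C1 neighbours the halogen
    ring = _benzene(b, c1_pos - 1.39 * _X, _Z, "L", 1, ref_in_plane=_X)
    x = b.add(element.capitalize(), element, origin, "LIG", "L", 1, True)
    if acc_offset is not None:
        off = np.array([acc_offset[0], acc_offset[1], 0.0])
        dist = float(np.linalg.norm(off))
        u = off / dist
        don_rad = math.acos(max(-1.0, min(1.0, -u[0])))
    else:
        don_rad = math.radians(don_angle)
        u = np.array([-math.cos(don_rad), math.sin(don_rad), 0.0])
    acc_pos = origin + dist * u
    acc_rad = math.radians(acc_angle)
    w = np.array([math.sin(don_rad), math.cos(don_rad), 0.0])
    v = math.cos(acc_rad) * (-u) + math.sin(acc_rad) * _unit(
        w - np.dot(w, u) * u)
    y_pos = acc_pos + 1.23 * v
    acc, y = _gly_acceptor(b, acc_pos, v, "A", 1)
    del y_pos
    return lambda: _expect_halogen(man, cfg, x, ring[0], acc, y)


_OCTAHEDRAL_DIRS = [_X, -_X, _Y, -_Y, _Z, -_Z]


def _plant_metal(b, man, cfg, origin, dist, n_partners, label):
    metal = b.add("MG", "MG", origin, "MG", "L", 1, True)
    targets = []
    for i in range(n_partners):
        w = _water(b, origin + dist * _OCTAHEDRAL_DIRS[i], "W", i + 1)
        targets.append(w)
    _ala_contact(b, origin + 6.8 * _unit(_X + _Y + _Z), _X, "A", 1)
    return lambda: _expect_metal(man, cfg, metal, targets, label)


def _plant_hbond_nucleic(b, man, cfg, origin, dist):
    """Guanine N1-H donor (RNA ligand) against a GLY carbonyl acceptor:
    a nucleic ligand forming a sequence-specific hydrogen bond."""
    atoms = _guanine(b, origin, "R", 1, resname="G", with_n1_h=True)
    n1, h1 = atoms["N1"], atoms["H1"]
    direction = _unit(h1.coords - n1.coords)
    # tilt the approach away from the exocyclic N2 donor so only the planted
    # N1-H...O bond forms
    away_n2 = atoms["N1"].coords - atoms["N2"].coords
    w = _unit(away_n2 - np.dot(away_n2, direction) * direction)
    tilted = _unit(math.cos(math.radians(35)) * direction
                   + math.sin(math.radians(35)) * w)
    acc_pos = n1.coords + dist * tilted
    acc, _c = _gly_acceptor(b, acc_pos, tilted, "A", 1)
    return lambda: _expect_hbond(man, cfg, n1, h1, acc)


def _plant_pication_nucleic(b, man, cfg, origin, dist):
    """Arg guanidinium stacked face-on over a guanine base (RNA ligand)."""
    atoms = _guanine(b, origin, "R", 1, resname="G")
    ring6 = [atoms[n] for n in ("N1", "C2", "N3", "C4", "C5", "C6")]
    ring5 = [atoms[n] for n in ("C4", "C5", "N7", "C8", "N9")]
    fused = list(dict.fromkeys(ring6 + ring5))
    c6, _, _ = fit_plane([a.coords for a in ring6])
    cz = c6 + dist * _Z
    cz_a, nh1, nh2, ne = _arg_guanidinium(b, cz, _Y, _X, _Z, "A", 1)
    charge = [cz_a, nh1, nh2, ne]

    def expect():
        # the detector keeps one record per ring system: the closest of the
        # 6-ring, 5-ring and fused-ring representations
        cands = []
        for ring in (ring6, ring5, fused):
            c, n, _ = fit_plane([a.coords for a in ring])
            cc = np.mean([a.coords for a in charge], axis=0)
            d = distance(c, cc)
            if d > cfg.pication_dist_max:
                continue
            from .geometry import vector_angle_deg
            ang = vector_angle_deg(n, cc - c)
            ang = min(ang, 180.0 - ang)
            if ang > cfg.pication_face_angle_max:
                continue
            cands.append((d, ring))
        if cands:
            d, ring = min(cands, key=lambda t: t[0])
            man.add("pication", {
                "ring_serials": frozenset(a.serial for a in ring),
                "charge_serials": frozenset(a.serial for a in charge),
                "dist": d})
    return expect


def _plant_halogen_nucleic(b, man, cfg, origin, dist, don_angle, acc_angle):
    """Bromobenzene donor against a DNA phosphate oxygen, with the DNA as
    receptor (nucleic-receptor mode)."""
    expect_base = _plant_halogen(b, man, cfg, origin, dist, don_angle,
                                 acc_angle, element="BR")
    # replace the GLY acceptor with a DG phosphate: remove GLY atoms
    gly = [a for a in b.atoms if a.resname == "GLY"]
    for a in gly:
        b.atoms.remove(a)
    x = next(a for a in b.atoms if a.element == "BR")
    c1 = next(a for a in b.atoms if a.name == "C1" and a.chain == "L")
    don_rad = math.radians(don_angle)
    u = np.array([-math.cos(don_rad), math.sin(don_rad), 0.0])
    acc_pos = x.coords + dist * u
    acc_rad = math.radians(acc_angle)
    w = np.array([math.sin(don_rad), math.cos(don_rad), 0.0])
    v = math.cos(acc_rad) * (-u) + math.sin(acc_rad) * _unit(
        w - np.dot(w, u) * u)
    p_pos = acc_pos + 1.48 * v
    op1 = b.add("OP1", "O", acc_pos, "DG", "D", 1, False)
    p = b.add("P", "P", p_pos, "DG", "D", 1, False)
    b.add("OP2", "O", p_pos + 1.48 * _unit(v + _Z), "DG", "D", 1, False)
    b.add("O5'", "O", p_pos + 1.59 * _unit(v - _Z), "DG", "D", 1, False)
    # base far away so only the backbone is in play
    _guanine(b, p_pos + np.array([0.0, 9.0, 0.0]), "D", 1, resname="DG")
    del expect_base, c1
    man.mode_flags["nucleic_acids_as_receptor"] = True
    return lambda: _expect_halogen(man, cfg, x, next(
        a for a in b.atoms if a.name == "C1" and a.chain == "L"), op1, p)


# ---------------------------------------------------------------------------

_PLANTERS = {
    "hydrophobic": _plant_hydrophobic,
    "hydrophobic_cluster": _plant_hydrophobic_cluster,
    "hbond": _plant_hbond,
    "water_bridge": _plant_water_bridge,
    "salt_bridge": _plant_salt_bridge,
    "pistack": _plant_pistack,
    "pication": _plant_pication,
    "halogen": _plant_halogen,
    "metal": _plant_metal,
    "hbond_nucleic": _plant_hbond_nucleic,
    "pication_nucleic": _plant_pication_nucleic,
    "halogen_nucleic": _plant_halogen_nucleic,
}


def generate_fixture(spec, seed: int = 0, jitter: float = 0.0,
                     cfg: ThresholdConfig = None, name: str = ""):
    """Write a synthetic PDB fixture for a list of planted interactions.

    ``spec`` is a list of ``{"type": ..., **params}`` dicts; each planted
    unit is placed in its own 40 A cell so units cannot interact. Returns
    ``(pdb_text, FixtureManifest)``. With a fixed seed the output is
    byte-identical across runs.
    """
    cfg = cfg or ThresholdConfig()
    b = _Builder()
    man = FixtureManifest(name=name)
    expect_fns = []
    for i, item in enumerate(spec):
        params = dict(item)
        itype = params.pop("type")
        origin = np.array([40.0 * i, 0.0, 0.0])
        planter = _PLANTERS.get(itype)
        if planter is None:
            raise FixtureError(f"unknown planted interaction type {itype!r}")
        expect_fns.append(planter(b, man, cfg, origin, **params))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        b.jitter(rng, jitter)
    b.quantize()
    b.check_clashes()
    for fn in expect_fns:
        fn()
    man.atom_counts = [len(b.atoms)]
    return b.to_pdb(), man


def multimodel_fixture(n_models: int = 2, seed: int = 0):
    """A small multi-model (NMR-like) fixture; the manifest records the
    atom count of every model."""
    texts = []
    counts = []
    for m in range(n_models):
        b = _Builder()
        shift = np.array([0.0, 0.0, 2.0 * m])
        b.add("C1", "C", shift, "LIG", "L", 1, True)
        b.add("C2", "C", shift - 1.53 * _X, "LIG", "L", 1, True)
        _ala_contact(b, shift + 3.8 * _X, _X, "A", 1)
        b.quantize()
        counts.append(len(b.atoms))
        body = b.to_pdb().replace("END\n", "")
        texts.append(f"MODEL     {m + 1:4d}\n{body}ENDMDL\n")
    man = FixtureManifest(name=f"multimodel_{n_models}")
    man.atom_counts = counts
    return "".join(texts) + "END\n", man


def nucleic_complex_fixture():
    """A FUS-like synthetic complex: a five-residue RNA chain (UGGUG) as
    ligand against protein residues planting a pi-stack on G2, a pi-cation
    on G2 and a salt bridge to the G3 phosphate."""
    cfg = ThresholdConfig()
    b = _Builder()
    man = FixtureManifest(name="nucleic_complex")
    spread = 22.0
    rna = []
    for i, resname in enumerate(["U", "G", "G", "U", "G"], start=1):
        origin = np.array([spread * (i - 1), 0.0, 0.0])
        if resname == "G":
            atoms = _guanine(b, origin, "R", i, resname="G",
                             with_phosphate=(i == 3))
        else:
            atoms = _uracil(b, origin, "R", i, resname="U")
        rna.append((resname, atoms))

    # pi-stack: PHE ring parallel over the G2 six-ring at 3.8 A
    g2 = rna[1][1]
    ring6 = [g2[n] for n in ("N1", "C2", "N3", "C4", "C5", "C6")]
    ring5 = [g2[n] for n in ("C4", "C5", "N7", "C8", "N9")]
    fused = list(dict.fromkeys(ring6 + ring5))
    c6, _, _ = fit_plane([a.coords for a in ring6])
    phe_ring = _phe_ring(b, c6 + 3.8 * _Z, _Z, "A", 101, ref_in_plane=_Y)

    # pi-cation: ARG guanidinium face-on under the G2 six-ring at 4.0 A
    cz = c6 - 4.0 * _Z
    cz_a, nh1, nh2, ne = _arg_guanidinium(b, cz, _Y, _X, -_Z, "A", 102)
    charge = [cz_a, nh1, nh2, ne]

    # salt bridge: LYS ammonium at 4.0 A from the G3 phosphate centroid,
    # approaching from the side facing away from the base
    g3 = rna[2][1]
    pc = (g3["OP1"].coords + g3["OP2"].coords) / 2
    base_centroid = np.mean(
        [g3[n].coords for n in ("N1", "C2", "N3", "C4", "C5", "C6",
                                "N7", "C8", "N9")], axis=0)
    away = _unit(pc - base_centroid)
    nz = _lys_cation(b, pc + 4.0 * away, away, "A", 103)

    b.quantize()
    b.check_clashes()

    # expectations (stacking: best representation among 6/5/fused rings)
    best = None
    for ring in (ring6, ring5, fused):
        c1, n1, _ = fit_plane([a.coords for a in ring])
        c2, n2, _ = fit_plane([a.coords for a in phe_ring])
        d = distance(c1, c2)
        if d > cfg.pistack_dist_max:
            continue
        ang = plane_angle_deg(n1, n2)
        if ang > cfg.pistack_ang_dev and ang < 90 - cfg.pistack_ang_dev:
            continue
        off = min(ring_offset(c1, n1, c2), ring_offset(c2, n2, c1))
        if off > cfg.pistack_offset_max:
            continue
        if best is None or (off, d) < (best[0], best[1]):
            best = (off, d, ring, "P" if ang <= cfg.pistack_ang_dev else "T",
                    ang)
    if best is not None:
        off, d, ring, stype, ang = best
        man.add("pistack", {
            "lig_serials": frozenset(a.serial for a in ring),
            "rec_serials": frozenset(a.serial for a in phe_ring),
            "dist": d, "stack_type": stype, "angle": ang, "offset": off})

    cands = []
    for ring in (ring6, ring5, fused):
        c, n, _ = fit_plane([a.coords for a in ring])
        cc = np.mean([a.coords for a in charge], axis=0)
        d = distance(c, cc)
        from .geometry import vector_angle_deg
        ang = min(vector_angle_deg(n, cc - c),
                  180 - vector_angle_deg(n, cc - c))
        if d <= cfg.pication_dist_max and ang <= cfg.pication_face_angle_max:
            cands.append((d, ring))
    if cands:
        d, ring = min(cands, key=lambda t: t[0])
        man.add("pication", {
            "ring_serials": frozenset(a.serial for a in ring),
            "charge_serials": frozenset(a.serial for a in charge),
            "dist": d})

    _expect_salt_bridge(man, cfg, [nz], [g3["OP1"], g3["OP2"]])
    man.atom_counts = [len(b.atoms)]
    return b.to_pdb(), man


def standard_suite(cfg: ThresholdConfig = None):
    """The planted fixture suite: for every interaction type one fixture
    inside its thresholds, one exactly at the boundary (inclusive rules must
    report it) and one outside."""
    cfg = cfg or ThresholdConfig()
    fixtures = []

    def add(name, spec, **kw):
        text, man = generate_fixture(spec, cfg=cfg, name=name, **kw)
        fixtures.append((name, text, man))

    add("hydrophobic_inside", [{"type": "hydrophobic", "dist": 3.8}])
    add("hydrophobic_boundary", [{"type": "hydrophobic",
                                  "dist": cfg.hydroph_dist_max}])
    add("hydrophobic_outside", [{"type": "hydrophobic", "dist": 4.2}])
    add("hydrophobic_cluster", [{"type": "hydrophobic_cluster"}])

    add("hbond_inside", [{"type": "hbond", "dist": 2.9, "angle": 165.0}])
    add("hbond_boundary", [{"type": "hbond", "dist": cfg.hbond_dist_max,
                            "angle": cfg.hbond_don_angle_min + 0.2}])
    add("hbond_outside_angle", [{"type": "hbond", "dist": 2.9, "angle": 80.0}])
    add("hbond_outside_dist", [{"type": "hbond", "dist": 4.3, "angle": 165.0}])

    add("water_bridge_inside", [{"type": "water_bridge", "leg1": 2.8,
                                 "leg2": 2.8, "omega": 110.0}])
    # exact 4.1 A leg via the (0.9, 4.0) right triangle; omega ~102.7 deg
    add("water_bridge_boundary", [{"type": "water_bridge",
                                   "leg1": cfg.water_bridge_mindist,
                                   "leg2": cfg.water_bridge_maxdist,
                                   "omega": 102.68,
                                   "acc_offset": (0.9, 4.0)}])
    add("water_bridge_outside", [{"type": "water_bridge", "leg1": 4.5,
                                  "leg2": 2.8, "omega": 110.0}])

    add("salt_bridge_inside", [{"type": "salt_bridge", "dist": 4.0}])
    add("salt_bridge_boundary", [{"type": "salt_bridge",
                                  "dist": cfg.saltbridge_dist_max}])
    add("salt_bridge_outside", [{"type": "salt_bridge", "dist": 6.0}])

    add("pistack_parallel", [{"type": "pistack", "dist": 3.8, "angle": 0.0,
                              "offset": 0.5}])
    # zero offset: symmetric rings give exact centroids, so the centroid
    # distance is exactly at the cutoff after quantisation
    add("pistack_boundary", [{"type": "pistack", "dist": cfg.pistack_dist_max,
                              "angle": 0.0, "offset": 0.0}])
    add("pistack_tshape", [{"type": "pistack", "dist": 5.0, "angle": 90.0,
                            "offset": 1.0, "t_shaped": True}])
    add("pistack_outside_angle", [{"type": "pistack", "dist": 5.0,
                                   "angle": 45.0, "offset": 0.5}])

    add("pication_inside", [{"type": "pication", "dist": 4.0}])
    add("pication_boundary", [{"type": "pication",
                               "dist": cfg.pication_dist_max}])
    add("pication_inplane", [{"type": "pication", "dist": 4.0,
                              "in_plane": True}])

    add("halogen_inside", [{"type": "halogen", "dist": 3.3,
                            "don_angle": 170.0, "acc_angle": 120.0}])
    # exact 4.0 A X...A distance via the (3.2, 2.4) right triangle; the
    # resulting donor angle (143.1 deg) is inside the +-30 deg window
    add("halogen_boundary", [{"type": "halogen", "dist": cfg.halogen_dist_max,
                              "don_angle": 143.13, "acc_angle": 120.0,
                              "acc_offset": (3.2, 2.4)}])
    add("halogen_outside", [{"type": "halogen", "dist": 3.3,
                             "don_angle": 120.0, "acc_angle": 120.0}])

    add("metal_octahedral", [{"type": "metal", "dist": 2.1, "n_partners": 6,
                              "label": "octahedral"}])
    add("metal_boundary", [{"type": "metal", "dist": cfg.metal_dist_max,
                            "n_partners": 1,
                            "label": "other/underdetermined"}])
    add("metal_outside", [{"type": "metal", "dist": 3.4, "n_partners": 1,
                           "label": "other/underdetermined"}])

    add("hbond_nucleic", [{"type": "hbond_nucleic", "dist": 2.9}])
    add("pication_nucleic", [{"type": "pication_nucleic", "dist": 4.0}])
    add("halogen_nucleic", [{"type": "halogen_nucleic", "dist": 3.4,
                             "don_angle": 170.0, "acc_angle": 120.0}])
    return fixtures


# ---------------------------------------------------------------------------
# manifest comparison

_GEOM_KEYS = {"dist", "dist_da", "angle", "dist_donor_water",
              "dist_acceptor_water", "omega", "don_angle", "acc_angle",
              "offset"}
_DIST_TOL = 0.01
_ANGLE_TOL = 0.1
_ANGLE_KEYS = {"angle", "omega", "don_angle", "acc_angle"}


def _reported_records(result) -> dict:
    """Canonical per-type record dicts from a ProfileResult, in the same
    shape the manifests use."""
    out: dict = {}

    def add(itype, rec):
        out.setdefault(itype, []).append(rec)

    for sr in result.sites:
        for c in sr.interactions.get("hydrophobic", []):
            add("hydrophobic", {"lig_serial": c.lig_atom.serial,
                                "rec_serial": c.rec_atom.serial,
                                "dist": c.dist})
        for hb in sr.interactions.get("hbond", []):
            rec = {"donor_serial": hb.donor.serial,
                   "acceptor_serial": hb.acceptor.serial,
                   "dist_da": hb.dist_da}
            if hb.angle is not None:
                rec["angle"] = hb.angle
            add("hbond", rec)
        for wb in sr.interactions.get("water_bridge", []):
            add("water_bridge", {"donor_serial": wb.donor.serial,
                                 "acceptor_serial": wb.acceptor.serial,
                                 "water_serial": wb.water_oxygen.serial,
                                 "dist_donor_water": wb.dist_donor_water,
                                 "dist_acceptor_water": wb.dist_acceptor_water,
                                 "omega": wb.omega})
        for sb in sr.interactions.get("salt_bridge", []):
            add("salt_bridge", {
                "pos_serials": frozenset(a.serial for a in sb.pos_center.atoms),
                "neg_serials": frozenset(a.serial for a in sb.neg_center.atoms),
                "dist": sb.dist})
        for ps in sr.interactions.get("pistack", []):
            add("pistack", {
                "lig_serials": frozenset(a.serial for a in ps.lig_ring.atoms),
                "rec_serials": frozenset(a.serial for a in ps.rec_ring.atoms),
                "dist": ps.dist, "stack_type": ps.stack_type,
                "angle": ps.angle, "offset": ps.offset})
        for pc in sr.interactions.get("pication", []):
            add("pication", {
                "ring_serials": frozenset(a.serial for a in pc.ring.atoms),
                "charge_serials": frozenset(a.serial for a in pc.charge.atoms),
                "dist": pc.dist})
        for xb in sr.interactions.get("halogen", []):
            add("halogen", {"halogen_serial": xb.halogen.serial,
                            "acceptor_serial": xb.acceptor.serial,
                            "dist": xb.dist, "don_angle": xb.don_angle,
                            "acc_angle": xb.acc_angle})
        for mc in sr.interactions.get("metal", []):
            add("metal", {"metal_serial": mc.metal.serial,
                          "target_serial": mc.target.serial, "dist": mc.dist,
                          "geometry": mc.geometry_label,
                          "coordination_number": mc.coordination_number})
    return out


def _key_of(rec: dict) -> tuple:
    return tuple(sorted((k, v) for k, v in rec.items()
                        if k not in _GEOM_KEYS))


def evaluate_fixture(result, manifest: FixtureManifest) -> list:
    """Compare a profiling result against a fixture manifest.

    Returns a list of mismatch descriptions (empty = exact agreement:
    same interactions by type and participants, geometry within
    0.01 A / 0.1 deg).
    """
    reported = _reported_records(result)
    mismatches = []
    all_types = set(reported) | set(manifest.expected)
    for itype in sorted(all_types):
        got = {(_key_of(r)): r for r in reported.get(itype, [])}
        want = {(_key_of(r)): r for r in manifest.expected.get(itype, [])}
        for key in want:
            if key not in got:
                mismatches.append(f"{manifest.name}: missing {itype} {key}")
        for key in got:
            if key not in want:
                mismatches.append(f"{manifest.name}: unexpected {itype} {key}")
        for key in set(got) & set(want):
            for gk in _GEOM_KEYS & set(want[key]):
                tol = _ANGLE_TOL if gk in _ANGLE_KEYS else _DIST_TOL
                if abs(got[key][gk] - want[key][gk]) > tol:
                    mismatches.append(
                        f"{manifest.name}: {itype} {gk} "
                        f"{got[key][gk]:.3f} != {want[key][gk]:.3f}")
    return mismatches
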