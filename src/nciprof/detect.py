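"""Geometric rule-based matching and filtering of non-covalent interactions.

One detector per interaction class: hydrophobic contacts, hydrogen bonds,
water bridges, salt bridges, pi-stacking, pi-cation interactions, halogen
bonds and metal complexes. Every rule is a set of inclusive distance/angle
thresholds from :class:`~nciprof.config.ThresholdConfig`; raw matches are
then refined deterministically (clustering of hydrophobic contacts,
suppression of redundant records subsumed by stronger ones).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ThresholdConfig
from .features import FeatureSet
from .geometry import (angle_deg, distance, plane_angle_deg, ring_offset,
                       vector_angle_deg)

__all__ = [
    "HydrophobicContact", "HydrogenBond", "WaterBridge", "SaltBridge",
    "PiStack", "PiCation", "HalogenBond", "MetalComplex",
    "detect_hydrophobic", "detect_hbonds", "detect_water_bridges",
    "detect_salt_bridges", "detect_pistacking", "detect_pication",
    "detect_halogen_bonds", "detect_metal_complexes",
    "detect_all", "refine_interactions", "INTERACTION_ORDER",
]

#: fixed catalogue order used everywhere reports are written
INTERACTION_ORDER = ("hydrophobic", "hbond", "water_bridge", "salt_bridge",
                     "pistack", "pication", "halogen", "metal")


def _res_label(atom) -> str:
    return atom.parent.label if atom.parent is not None else "?"


@dataclass
class HydrophobicContact:
    itype = "hydrophobic"
    lig_atom: object
    rec_atom: object
    dist: float

    @property
    def rec_residue(self):
        return self.rec_atom.parent

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist": self.dist}

    def sort_key(self):
        return (self.rec_residue.key, self.dist, self.rec_atom.serial,
                self.lig_atom.serial)


@dataclass
class HydrogenBond:
    itype = "hbond"
    donor: object                  # Atom
    acceptor: object               # Atom
    hydrogen: Optional[object]
    dist_da: float
    dist_ha: Optional[float]
    angle: Optional[float]         # D-H...A, None when distance-only
    donor_is_ligand: bool
    unverified: bool = False       # donor had no placeable hydrogen

    @property
    def rec_atom(self):
        return self.acceptor if self.donor_is_ligand else self.donor

    @property
    def lig_atom(self):
        return self.donor if self.donor_is_ligand else self.acceptor

    @property
    def rec_residue(self):
        return self.rec_atom.parent

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        g = {"dist_da": self.dist_da}
        if self.dist_ha is not None:
            g["dist_ha"] = self.dist_ha
        if self.angle is not None:
            g["angle"] = self.angle
        return g

    def sort_key(self):
        return (self.rec_residue.key, self.dist_da, self.donor.serial,
                self.acceptor.serial)


@dataclass
class WaterBridge:
    itype = "water_bridge"
    donor: object                  # polar atom donating via the water
    acceptor: object               # polar atom accepting via the water
    water_oxygen: object
    dist_donor_water: float
    dist_acceptor_water: float
    omega: float                   # donor-Owat-acceptor angle at the water
    donor_is_ligand: bool

    @property
    def lig_atom(self):
        return self.donor if self.donor_is_ligand else self.acceptor

    @property
    def rec_atom(self):
        return self.acceptor if self.donor_is_ligand else self.donor

    @property
    def rec_residue(self):
        return self.rec_atom.parent

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist_donor_water": self.dist_donor_water,
                "dist_acceptor_water": self.dist_acceptor_water,
                "omega": self.omega}

    def sort_key(self):
        return (self.rec_residue.key, self.dist_donor_water,
                self.water_oxygen.serial, self.donor.serial)


@dataclass
class SaltBridge:
    itype = "salt_bridge"
    pos_center: object             # ChargedCenter
    neg_center: object
    dist: float
    pos_is_ligand: bool

    @property
    def lig_center(self):
        return self.pos_center if self.pos_is_ligand else self.neg_center

    @property
    def rec_center(self):
        return self.neg_center if self.pos_is_ligand else self.pos_center

    @property
    def rec_residue(self):
        return self.rec_center.residue

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist": self.dist}

    def sort_key(self):
        return (self.rec_residue.key, self.dist)


@dataclass
class PiStack:
    itype = "pistack"
    lig_ring: object
    rec_ring: object
    dist: float                    # centroid-centroid
    angle: float                   # interplanar, folded into [0, 90]
    offset: float
    stack_type: str                # "P" parallel | "T" T-shaped

    @property
    def rec_residue(self):
        return self.rec_ring.residue

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist": self.dist, "angle": self.angle, "offset": self.offset}

    def sort_key(self):
        return (self.rec_residue.key, self.dist, self.offset)


@dataclass
class PiCation:
    itype = "pication"
    ring: object
    charge: object                 # positive ChargedCenter
    dist: float
    ring_is_ligand: bool

    @property
    def rec_residue(self):
        return (self.charge.residue if self.ring_is_ligand
                else self.ring.residue)

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist": self.dist}

    def sort_key(self):
        return (self.rec_residue.key, self.dist)


@dataclass
class HalogenBond:
    itype = "halogen"
    halogen: object                # Atom (ligand side)
    carbon: object                 # its bound carbon
    acceptor: object               # Atom (receptor side)
    acceptor_y: object             # heavy atom bound to the acceptor
    dist: float
    don_angle: float               # C-X...A
    acc_angle: float               # Y-A...X

    @property
    def lig_atom(self):
        return self.halogen

    @property
    def rec_atom(self):
        return self.acceptor

    @property
    def rec_residue(self):
        return self.acceptor.parent

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist": self.dist, "don_angle": self.don_angle,
                "acc_angle": self.acc_angle}

    def sort_key(self):
        return (self.rec_residue.key, self.dist, self.halogen.serial)


@dataclass
class MetalComplex:
    itype = "metal"
    metal: object                  # Atom
    target: object                 # coordinating Atom
    dist: float
    geometry_label: str            # idealised sphere geometry
    coordination_number: int
    rmsd: float                    # angular RMSD of the best template fit
    target_is_ligand: bool
    metal_is_ligand: bool

    @property
    def rec_residue(self):
        if not self.target_is_ligand:
            return self.target.parent
        return self.metal.parent

    @property
    def receptor_is_nucleic(self):
        return self.rec_residue.is_nucleic

    def geometry(self) -> dict:
        return {"dist": self.dist}

    def sort_key(self):
        return (self.rec_residue.key, self.metal.serial, self.dist,
                self.target.serial)


# ---------------------------------------------------------------------------
# detectors

def detect_hydrophobic(lig: FeatureSet, rec: FeatureSet,
                       cfg: ThresholdConfig, refine: bool = True) -> list:
    """Ligand-carbon/receptor-carbon pairs within the hydrophobic cutoff,
    reduced by the two-stage clustering rule."""
    raw = []
    for hl, hr in itertools.product(lig.hydrophobics, rec.hydrophobics):
        d = hl.atom.distance_to(hr.atom)
        if d <= cfg.hydroph_dist_max:
            raw.append(HydrophobicContact(hl.atom, hr.atom, d))
    return _cluster_hydrophobic(raw) if refine else raw


def _cluster_hydrophobic(contacts: list) -> list:
    if not contacts:
        return []
    # stage 1: per (ligand atom, receptor residue) keep the closest pair
    best = {}
    for c in contacts:
        key = (c.lig_atom, c.rec_residue)
        cur = best.get(key)
        if cur is None or (c.dist, c.rec_atom.serial, c.lig_atom.serial) < \
                (cur.dist, cur.rec_atom.serial, cur.lig_atom.serial):
            best[key] = c
    kept = list(best.values())
    # stage 2: fully connected clusters collapse to their closest contact
    import networkx as nx
    g = nx.Graph()
    for c in kept:
        g.add_edge(("L", c.lig_atom), ("R", c.rec_atom), contact=c)
    out = []
    for comp in nx.connected_components(g):
        edges = [g.edges[e]["contact"] for e in g.subgraph(comp).edges]
        lig_nodes = [n for n in comp if n[0] == "L"]
        rec_nodes = [n for n in comp if n[0] == "R"]
        if len(edges) == len(lig_nodes) * len(rec_nodes) and len(edges) > 1:
            out.append(min(edges, key=lambda c: (
                c.dist, c.rec_atom.serial, c.lig_atom.serial)))
        else:
            out.extend(edges)
    return sorted(out, key=HydrophobicContact.sort_key)


def _hbond_pairs(donors, acceptors, cfg, donor_is_ligand):
    out = []
    for don in donors:
        for acc in acceptors:
            a = acc.acceptor_atom
            d_atom = don.donor_atom
            if a is d_atom:
                continue
            d_da = d_atom.distance_to(a)
            if d_da > cfg.hbond_dist_max or d_da < 1.5:
                continue
            if don.missing_h or not don.hydrogens:
                out.append(HydrogenBond(d_atom, a, None, d_da, None, None,
                                        donor_is_ligand, unverified=True))
                continue
            best = None
            for h in don.hydrogens:
                ang = angle_deg(d_atom.coords, h.coords, a.coords)
                if ang >= cfg.hbond_don_angle_min:
                    d_ha = h.distance_to(a)
                    if best is None or d_ha < best[1]:
                        best = (h, d_ha, ang)
            if best is not None:
                out.append(HydrogenBond(d_atom, a, best[0], d_da, best[1],
                                        best[2], donor_is_ligand))
    return out


def detect_hbonds(lig: FeatureSet, rec: FeatureSet,
                  cfg: ThresholdConfig) -> list:
    """Hydrogen bonds in both directions: heavy-atom distance within the
    cutoff and donor angle D-H...A at or above the minimum."""
    out = _hbond_pairs(lig.donors, rec.acceptors, cfg, donor_is_ligand=True)
    out += _hbond_pairs(rec.donors, lig.acceptors, cfg, donor_is_ligand=False)
    return sorted(out, key=HydrogenBond.sort_key)


def detect_water_bridges(lig: FeatureSet, rec: FeatureSet,
                         waters: list, cfg: ThresholdConfig) -> list:
    """Hydrogen-bond relays through a shared water oxygen.

    Each leg must fall inside the water-bridge distance window and the
    polar-Owat-polar angle inside the omega window; one leg is donor-like
    and the other acceptor-like.
    """
    lig_donors = [d.donor_atom for d in lig.donors]
    lig_accept = [a.acceptor_atom for a in lig.acceptors]
    rec_donors = [d.donor_atom for d in rec.donors]
    rec_accept = [a.acceptor_atom for a in rec.acceptors]
    out = []
    seen = set()
    for w in waters:
        wo = w.atom
        for l_don, r_acc in itertools.product(lig_donors, rec_accept):
            rec_ = _water_bridge_check(l_don, r_acc, wo, cfg, True)
            if rec_ is not None:
                key = (l_don.serial, r_acc.serial, wo.serial)
                if key not in seen:
                    seen.add(key)
                    out.append(rec_)
        for r_don, l_acc in itertools.product(rec_donors, lig_accept):
            rec_ = _water_bridge_check(r_don, l_acc, wo, cfg, False)
            if rec_ is not None:
                key = (r_don.serial, l_acc.serial, wo.serial)
                if key not in seen:
                    seen.add(key)
                    out.append(rec_)
    return sorted(out, key=WaterBridge.sort_key)


def _water_bridge_check(donor, acceptor, water_o, cfg, donor_is_ligand):
    if donor is acceptor:
        return None
    d_dw = donor.distance_to(water_o)
    d_aw = acceptor.distance_to(water_o)
    if not (cfg.water_bridge_mindist <= d_dw <= cfg.water_bridge_maxdist):
        return None
    if not (cfg.water_bridge_mindist <= d_aw <= cfg.water_bridge_maxdist):
        return None
    omega = angle_deg(donor.coords, water_o.coords, acceptor.coords)
    if not (cfg.water_bridge_omega_min <= omega <= cfg.water_bridge_omega_max):
        return None
    return WaterBridge(donor, acceptor, water_o, d_dw, d_aw, omega,
                       donor_is_ligand)


def detect_salt_bridges(lig: FeatureSet, rec: FeatureSet,
                        cfg: ThresholdConfig) -> list:
    """Opposite-sign charged-centre pairs within the centroid cutoff."""
    out = []
    for pos, neg, pos_is_lig in itertools.chain(
            ((p, n, True) for p in lig.pos_charges for n in rec.neg_charges),
            ((p, n, False) for p in rec.pos_charges for n in lig.neg_charges)):
        d = distance(pos.centroid, neg.centroid)
        if d <= cfg.saltbridge_dist_max:
            out.append(SaltBridge(pos, neg, d, pos_is_lig))
    return sorted(out, key=SaltBridge.sort_key)


def detect_pistacking(lig: FeatureSet, rec: FeatureSet,
                      cfg: ThresholdConfig, refine: bool = True) -> list:
    """Parallel (P) or T-shaped (T) aromatic ring stacking."""
    out = []
    for rl, rr in itertools.product(lig.rings, rec.rings):
        d = distance(rl.centroid, rr.centroid)
        if d > cfg.pistack_dist_max:
            continue
        ang = plane_angle_deg(rl.normal, rr.normal)
        if ang <= cfg.pistack_ang_dev:
            stype = "P"
        elif ang >= 90.0 - cfg.pistack_ang_dev:
            stype = "T"
        else:
            continue
        offset = min(ring_offset(rl.centroid, rl.normal, rr.centroid),
                     ring_offset(rr.centroid, rr.normal, rl.centroid))
        if offset <= cfg.pistack_offset_max:
            out.append(PiStack(rl, rr, d, ang, offset, stype))
    if refine:
        out = _dedupe_stacks(out)
    return sorted(out, key=PiStack.sort_key)


def _dedupe_stacks(stacks: list) -> list:
    """One record per ring-system pair: multi-ring representations of a
    fused system (purines) keep only the best (smallest-offset) stack."""
    best = {}
    for s in stacks:
        key = (s.lig_ring.system_key, s.rec_ring.system_key)
        cur = best.get(key)
        if cur is None or (s.offset, s.dist) < (cur.offset, cur.dist):
            best[key] = s
    return list(best.values())


def detect_pication(lig: FeatureSet, rec: FeatureSet,
                    cfg: ThresholdConfig, refine: bool = True) -> list:
    """Cationic group over an aromatic ring face.

    Guanidinium (and amidinium) cations must additionally approach roughly
    face-on: angle between the ring normal and the centroid-to-cation
    vector at most ``pication_face_angle_max``.
    """
    out = []
    pairs = itertools.chain(
        ((ring, ch, True) for ring in lig.rings for ch in rec.pos_charges),
        ((ring, ch, False) for ring in rec.rings for ch in lig.pos_charges))
    for ring, charge, ring_is_lig in pairs:
        d = distance(ring.centroid, charge.centroid)
        if d > cfg.pication_dist_max:
            continue
        if charge.is_guanidinium:
            ang = vector_angle_deg(ring.normal, charge.centroid - ring.centroid)
            ang = min(ang, 180.0 - ang)
            if ang > cfg.pication_face_angle_max:
                continue
        out.append(PiCation(ring, charge, d, ring_is_lig))
    if refine:
        best = {}
        for p in out:
            key = (p.ring.system_key, id(p.charge))
            cur = best.get(key)
            if cur is None or p.dist < cur.dist:
                best[key] = p
        out = list(best.values())
    return sorted(out, key=PiCation.sort_key)


def detect_halogen_bonds(lig: FeatureSet, rec: FeatureSet,
                         cfg: ThresholdConfig, adjacency=None) -> list:
    """Directional sigma-hole contacts from ligand C-X groups to receptor
    electron donors (O/N/S with a known attached heavy atom)."""
    from .bonds import heavy_neighbors
    out = []
    for hd in lig.halogen_donors:
        x, c = hd.halogen, hd.carbon
        for acc in rec.acceptors:
            a = acc.acceptor_atom
            d = x.distance_to(a)
            if d > cfg.halogen_dist_max:
                continue
            don_ang = angle_deg(c.coords, x.coords, a.coords)
            if abs(don_ang - cfg.halogen_don_angle) > cfg.halogen_don_angle_dev:
                continue
            ys = heavy_neighbors(a, adjacency) if adjacency else []
            ys = [y for y in ys if y is not x]
            if not ys:
                continue  # acceptor's attached heavy atom must be known
            y = min(ys, key=lambda at: at.serial)
            acc_ang = angle_deg(y.coords, a.coords, x.coords)
            if abs(acc_ang - cfg.halogen_acc_angle) > cfg.halogen_acc_angle_dev:
                continue
            out.append(HalogenBond(x, c, a, y, d, don_ang, acc_ang))
    return sorted(out, key=HalogenBond.sort_key)


# idealised coordination templates as unit vectors
def _coordination_templates():
    s = 1 / np.sqrt(3)
    return {
        "linear": np.array([[1, 0, 0], [-1, 0, 0]], float),
        "trigonal.planar": np.array(
            [[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0], [-0.5, -np.sqrt(3) / 2, 0]]),
        "tetrahedral": np.array(
            [[s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]),
        "square.planar": np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float),
        "trigonal.bipyramidal": np.array(
            [[0, 0, 1], [0, 0, -1], [1, 0, 0],
             [-0.5, np.sqrt(3) / 2, 0], [-0.5, -np.sqrt(3) / 2, 0]]),
        "square.pyramidal": np.array(
            [[0, 0, 1], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float),
        "octahedral": np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
             [0, 0, 1], [0, 0, -1]], float),
    }


_TEMPLATES = _coordination_templates()


def _pairwise_angles(vectors) -> np.ndarray:
    angles = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            angles.append(vector_angle_deg(vectors[i], vectors[j]))
    return np.sort(np.asarray(angles))


def classify_coordination(metal_coords, target_coords):
    """Best idealised-geometry label for a coordination sphere.

    Compares the sorted multiset of observed pairwise target-metal-target
    angles against each canonical template of matching coordination number
    and returns ``(label, angular_rmsd)``.
    """
    n = len(target_coords)
    if n < 2:
        return "other/underdetermined", float("nan")
    vectors = [np.asarray(t, float) - np.asarray(metal_coords, float)
               for t in target_coords]
    observed = _pairwise_angles(vectors)
    best = ("other/underdetermined", float("inf"))
    for label, tpl in _TEMPLATES.items():
        if len(tpl) != n:
            continue
        expected = _pairwise_angles(tpl)
        rmsd = float(np.sqrt(np.mean((observed - expected) ** 2)))
        if rmsd < best[1]:
            best = (label, rmsd)
    if not np.isfinite(best[1]):
        return "other/underdetermined", float("nan")
    return best


def detect_metal_complexes(lig: FeatureSet, rec: FeatureSet,
                           waters: list, cfg: ThresholdConfig) -> list:
    """Coordination records for every metal-target pair within the cutoff.

    The full coordination sphere (targets from either side plus water
    oxygens) is grouped per metal and an idealised geometry label assigned;
    only complexes that involve the ligand at all are reported.
    """
    lig_targets = {a.acceptor_atom for a in lig.acceptors}
    lig_targets |= {d.donor_atom for d in lig.donors}
    lig_targets |= {at for ch in lig.neg_charges for at in ch.atoms
                    if at.element in ("O", "N", "S")}
    rec_targets = {a.acceptor_atom for a in rec.acceptors}
    rec_targets |= {d.donor_atom for d in rec.donors}
    rec_targets |= {at for ch in rec.neg_charges for at in ch.atoms
                    if at.element in ("O", "N", "S")}
    water_targets = {w.atom for w in waters}

    out = []
    for m, metal_is_lig in [(m, True) for m in lig.metals] + \
                           [(m, False) for m in rec.metals]:
        metal = m.atom
        sphere = []
        for t in sorted(lig_targets | rec_targets | water_targets,
                        key=lambda a: a.serial):
            if t is metal:
                continue
            d = metal.distance_to(t)
            if d <= cfg.metal_dist_max:
                sphere.append((t, d))
        if not sphere:
            continue
        label, rmsd = classify_coordination(
            metal.coords, [t.coords for t, _ in sphere])
        cn = len(sphere)
        for t, d in sphere:
            t_is_lig = t in lig_targets
            if not (metal_is_lig or t_is_lig):
                continue  # receptor-internal coordination: context only
            out.append(MetalComplex(metal, t, d, label, cn, rmsd,
                                    target_is_ligand=t_is_lig,
                                    metal_is_ligand=metal_is_lig))
    return sorted(out, key=MetalComplex.sort_key)


# ---------------------------------------------------------------------------
# refinement across interaction types

def refine_interactions(detected: dict, cfg: ThresholdConfig) -> dict:
    """Deterministic cross-type filtering of raw detector output.

    - a water bridge is suppressed when the same ligand-atom/receptor-atom
      pair forms a direct hydrogen bond;
    - hydrogen bonds between member atoms of two salt-bridged groups are
      subsumed by the salt bridge;
    - a salt bridge duplicating a pi-cation contact (same centroids) is
      dropped. Hydrophobic clustering and multi-ring stack deduplication
      already run inside their detectors.
    """
    out = dict(detected)

    hbond_pairs = {(hb.lig_atom, hb.rec_atom) for hb in out.get("hbond", [])}
    out["water_bridge"] = [wb for wb in out.get("water_bridge", [])
                           if (wb.lig_atom, wb.rec_atom) not in hbond_pairs]

    salt_members = []
    for sb in out.get("salt_bridge", []):
        salt_members.append((set(sb.pos_center.atoms), set(sb.neg_center.atoms)))
    kept_hb = []
    for hb in out.get("hbond", []):
        subsumed = any((hb.donor in g1 and hb.acceptor in g2) or
                       (hb.donor in g2 and hb.acceptor in g1)
                       for g1, g2 in salt_members)
        if not subsumed:
            kept_hb.append(hb)
    out["hbond"] = kept_hb

    pication_keys = set()
    for pc in out.get("pication", []):
        pication_keys.add((frozenset(a.serial for a in pc.ring.atoms),
                           frozenset(a.serial for a in pc.charge.atoms)))
    kept_sb = []
    for sb in out.get("salt_bridge", []):
        key = (frozenset(a.serial for a in sb.neg_center.atoms),
               frozenset(a.serial for a in sb.pos_center.atoms))
        if key not in pication_keys:
            kept_sb.append(sb)
    out["salt_bridge"] = kept_sb
    return out


def audit_interactions(detected: dict, cfg: ThresholdConfig) -> list:
    """Post-hoc check that every reported geometry satisfies the active
    thresholds; returns a list of violation strings (empty when clean)."""
    bad = []

    def check(ok, rec, what):
        if not ok:
            bad.append(f"{rec.itype}: {what}")

    for c in detected.get("hydrophobic", []):
        check(c.dist <= cfg.hydroph_dist_max, c, f"dist {c.dist:.2f}")
    for hb in detected.get("hbond", []):
        check(hb.dist_da <= cfg.hbond_dist_max, hb, f"dist {hb.dist_da:.2f}")
        if hb.angle is not None:
            check(hb.angle >= cfg.hbond_don_angle_min, hb,
                  f"angle {hb.angle:.1f}")
    for wb in detected.get("water_bridge", []):
        for d in (wb.dist_donor_water, wb.dist_acceptor_water):
            check(cfg.water_bridge_mindist <= d <= cfg.water_bridge_maxdist,
                  wb, f"leg {d:.2f}")
        check(cfg.water_bridge_omega_min <= wb.omega
              <= cfg.water_bridge_omega_max, wb, f"omega {wb.omega:.1f}")
    for sb in detected.get("salt_bridge", []):
        check(sb.dist <= cfg.saltbridge_dist_max, sb, f"dist {sb.dist:.2f}")
    for ps in detected.get("pistack", []):
        check(ps.dist <= cfg.pistack_dist_max, ps, f"dist {ps.dist:.2f}")
        check(ps.offset <= cfg.pistack_offset_max, ps, f"offset {ps.offset:.2f}")
        check(ps.angle <= cfg.pistack_ang_dev or
              ps.angle >= 90.0 - cfg.pistack_ang_dev, ps,
              f"angle {ps.angle:.1f}")
    for pc in detected.get("pication", []):
        check(pc.dist <= cfg.pication_dist_max, pc, f"dist {pc.dist:.2f}")
    for xb in detected.get("halogen", []):
        check(xb.dist <= cfg.halogen_dist_max, xb, f"dist {xb.dist:.2f}")
        check(abs(xb.don_angle - cfg.halogen_don_angle)
              <= cfg.halogen_don_angle_dev, xb, f"don angle {xb.don_angle:.1f}")
        check(abs(xb.acc_angle - cfg.halogen_acc_angle)
              <= cfg.halogen_acc_angle_dev, xb, f"acc angle {xb.acc_angle:.1f}")
    for mc in detected.get("metal", []):
        check(mc.dist <= cfg.metal_dist_max, mc, f"dist {mc.dist:.2f}")
    return bad


def detect_all(lig: FeatureSet, rec: FeatureSet, waters: list,
               cfg: ThresholdConfig, adjacency=None,
               refine: bool = True) -> dict:
    """Run all eight detectors and (optionally) the cross-type refinement."""
    detected = {
        "hydrophobic": detect_hydrophobic(lig, rec, cfg, refine=refine),
        "hbond": detect_hbonds(lig, rec, cfg),
        "water_bridge": detect_water_bridges(lig, rec, waters, cfg),
        "salt_bridge": detect_salt_bridges(lig, rec, cfg),
        "pistack": detect_pistacking(lig, rec, cfg, refine=refine),
        "pication": detect_pication(lig, rec, cfg, refine=refine),
        "halogen": detect_halogen_bonds(lig, rec, cfg, adjacency=adjacency),
        "metal": detect_metal_complexes(lig, rec, waters, cfg),
    }
    return refine_interactions(detected, cfg) if refine else detected
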