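"""Explicit-hydrogen inventory for hydrogen-bond donor geometry.

Polar donors need hydrogen positions so the donor angle D-H...A can be
evaluated. Hydrogens already present in the input are kept unmodified;
missing ones are placed with idealised sp2/sp3 rules: anti to the heavy
neighbours when the direction is determined, trigonal in-plane pairs for
sp2 -NH2 groups, staggered tetrahedral triplets for -NH3+, and rotatable
hydroxyl/water hydrogens oriented toward the nearest polar partner (a
deterministic stand-in for torsional optimisation). Donors whose geometry
prevents placement are flagged; detectors then evaluate them distance-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .bonds import heavy_neighbors, perceive_bonds
from .features import ligand_polar_roles
from .structure import Atom, Structure
from .templates import get_template

__all__ = ["HydrogenationReport", "ensure_hydrogens"]

_BOND_LENGTH = {"N": 1.01, "O": 0.96, "S": 1.34}
_SP3_COS = -1.0 / 3.0                 # cos(109.47 deg)
_SP2_COS = -0.5                       # cos(120 deg)
#: neutral histidine tautomer: NE2 protonated, ND1 left as acceptor
_PLACEMENT_OVERRIDES = {("HIS", "ND1"): 0}


@dataclass
class HydrogenationReport:
    """Per-residue account of the hydrogens added by :func:`ensure_hydrogens`."""

    added: dict = field(default_factory=dict)      # residue label -> count
    failed: list = field(default_factory=list)     # (residue label, atom name)

    @property
    def total_added(self) -> int:
        return sum(self.added.values())


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _any_orthogonal(v):
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(v)))] = 1.0
    return _unit(np.cross(v, axis))


def _donor_targets(structure: Structure):
    """KD-tree over polar atoms, used to orient rotatable hydrogens."""
    polar = [a for a in structure.atoms()
             if a.element in ("N", "O") and a.is_heavy]
    if not polar:
        return None, []
    return cKDTree(np.array([a.coords for a in polar])), polar


def _nearest_polar(donor, tree, polar, exclude):
    if tree is None:
        return None
    dists, idxs = tree.query(donor.coords, k=min(6, len(polar)))
    dists = np.atleast_1d(dists)
    idxs = np.atleast_1d(idxs)
    for d, i in zip(dists, idxs):
        cand = polar[int(i)]
        if cand in exclude or cand is donor or d > 4.0 or d < 0.5:
            continue
        return cand
    return None


def _place(donor, directions, next_serial):
    new = []
    length = _BOND_LENGTH.get(donor.element, 1.0)
    for i, d in enumerate(directions):
        pos = donor.coords + length * _unit(d)
        name = ("H" + donor.name[1:]) if len(donor.name) > 1 else "H"
        if len(directions) > 1 or len(name) >= 4:
            name = (name[:3] + str(i + 1))[:4]
        atom = Atom(serial=next_serial + i, name=name, element="H",
                    coords=pos, is_hetero=donor.is_hetero, parent=donor.parent)
        donor.parent.atoms.append(atom)
        new.append(atom)
    return new


def _directions_for(donor, need, adjacency, tree, polar):
    """Idealised directions for the missing hydrogens, or None on failure."""
    nbrs = heavy_neighbors(donor, adjacency)
    existing_h = [n for n in adjacency.get(donor, ()) if n.element == "H"]
    occupied = nbrs + existing_h

    if len(occupied) >= 2 and need == 1:
        s = sum((_unit(n.coords - donor.coords) for n in occupied),
                np.zeros(3))
        if np.linalg.norm(s) < 1e-6:
            return None
        return [-_unit(s)]

    if len(nbrs) == 1:
        a = nbrs[0]
        v = _unit(a.coords - donor.coords)
        ref = None
        for b in sorted(heavy_neighbors(a, adjacency), key=lambda x: x.serial):
            if b is not donor:
                ref = b
                break
        if ref is not None:
            w = ref.coords - a.coords
            u1 = _unit(w - np.dot(w, v) * v) if np.linalg.norm(
                w - np.dot(w, v) * v) > 1e-6 else _any_orthogonal(v)
        else:
            u1 = _any_orthogonal(v)
        u2 = _unit(np.cross(v, u1))
        if need == 2:      # sp2 -NH2: both in the (donor, A, ref) plane
            s = np.sqrt(1 - _SP2_COS ** 2)
            return [_SP2_COS * v + s * u1, _SP2_COS * v - s * u1]
        if need == 3:      # sp3 -NH3+: staggered relative to ref
            s = np.sqrt(1 - _SP3_COS ** 2)
            return [_SP3_COS * v + s * (np.cos(t) * u1 + np.sin(t) * u2)
                    for t in np.radians([60.0, 180.0, 300.0])]
        if need == 1:      # rotatable hydroxyl/thiol: orient toward a partner
            target = _nearest_polar(donor, tree, polar,
                                    exclude=set(occupied) | {a})
            cos_t = _SP3_COS if donor.element in ("O", "S") else _SP2_COS
            s = np.sqrt(1 - cos_t ** 2)
            if target is not None:
                w = target.coords - donor.coords
                perp = w - np.dot(w, v) * v
                u = _unit(perp) if np.linalg.norm(perp) > 1e-6 else u1
            else:
                u = -u1    # anti-periplanar to the reference atom
            return [cos_t * v + s * u]
    return None


def _water_directions(oxygen, existing_h, tree, polar):
    need = 2 - len(existing_h)
    if need <= 0:
        return []
    target = _nearest_polar(oxygen, tree, polar, exclude=set(existing_h))
    if existing_h:
        v = _unit(existing_h[0].coords - oxygen.coords)
    elif target is not None:
        v = _unit(target.coords - oxygen.coords)
    else:
        v = np.array([1.0, 0.0, 0.0])
    u = _any_orthogonal(v)
    cos_t = np.cos(np.radians(104.5))
    sin_t = np.sin(np.radians(104.5))
    second = cos_t * v + sin_t * u
    return [v, second][2 - need:]


def _donor_requirements(res, adjacency):
    """(atom, required H count) pairs for one residue."""
    reqs = []
    if res.kind == "water":
        return reqs  # handled separately
    if res.kind == "amino_acid":
        n = res.get_atom("N")
        if n is not None and res.name != "PRO":
            reqs.append((n, 1))
        tpl = get_template(res.name)
        if tpl:
            for name, count in tpl.donors.items():
                count = _PLACEMENT_OVERRIDES.get((res.name, name), count)
                a = res.get_atom(name)
                if a is not None and count > 0:
                    reqs.append((a, count))
    elif res.is_nucleic:
        tpl = get_template(res.name)
        if tpl:
            for name, count in tpl.donors.items():
                a = res.get_atom(name)
                if a is not None:
                    reqs.append((a, count))
        if res.kind == "rna":
            o2p = res.get_atom("O2'") or res.get_atom("O2*")
            if o2p is not None:
                reqs.append((o2p, 1))
    elif res.kind == "other_hetero":
        roles = ligand_polar_roles(res.atoms, adjacency)
        for a, role in roles.items():
            if role["donor_h"] > 0:
                reqs.append((a, role["donor_h"]))
    return reqs


def ensure_hydrogens(structure: Structure) -> HydrogenationReport:
    """Guarantee explicit hydrogens on every polar donor of the selected model.

    Idempotent: hydrogens already present (from the input or a previous
    call) are kept and counted toward each donor's requirement.
    """
    adjacency = perceive_bonds(list(structure.atoms()), structure.conect)
    tree, polar = _donor_targets(structure)
    report = HydrogenationReport()
    next_serial = max((a.serial for a in structure.atoms()), default=0) + 1

    for res in structure.residues():
        added_here = 0
        if res.kind == "water":
            oxy = next((a for a in res.atoms if a.element == "O"), None)
            if oxy is None:
                continue
            existing = [n for n in adjacency.get(oxy, ()) if n.element == "H"]
            dirs = _water_directions(oxy, existing, tree, polar)
            new = _place(oxy, dirs, next_serial)
            for h in new:
                adjacency.setdefault(oxy, set()).add(h)
                adjacency[h] = {oxy}
            next_serial += len(new)
            added_here += len(new)
        else:
            for donor, required in _donor_requirements(res, adjacency):
                existing = [n for n in adjacency.get(donor, ())
                            if n.element == "H"]
                need = required - len(existing)
                if need <= 0:
                    continue
                dirs = _directions_for(donor, need, adjacency, tree, polar)
                if dirs is None:
                    report.failed.append((res.label, donor.name))
                    continue
                new = _place(donor, dirs, next_serial)
                for h in new:
                    adjacency.setdefault(donor, set()).add(h)
                    adjacency[h] = {donor}
                next_serial += len(new)
                added_here += len(new)
        if added_here:
            report.added[res.label] = added_here
    return report
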