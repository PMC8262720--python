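"""Independent brute-force oracles for the geometric interaction rules.

Every function evaluates a rule over all candidate pairs with plain Python
loops and the math module - no numpy vectorisation, no KD-trees, no reuse of
the package's geometry helpers - so agreement with the detectors is a
meaningful cross-check rather than a tautology.
"""

import math


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _sub(p, q):
    return [a - b for a, b in zip(p, q)]


def _dot(u, v):
    return sum(a * b for a, b in zip(u, v))


def _norm(u):
    return math.sqrt(_dot(u, u))


def _angle_at(vertex, p, q):
    """Angle p-vertex-q in degrees."""
    u = _sub(p, vertex)
    v = _sub(q, vertex)
    c = _dot(u, v) / (_norm(u) * _norm(v))
    c = max(-1.0, min(1.0, c))
    return math.degrees(math.acos(c))


def _vec_angle(u, v):
    c = _dot(u, v) / (_norm(u) * _norm(v))
    c = max(-1.0, min(1.0, c))
    return math.degrees(math.acos(c))


def _mean(points):
    n = len(points)
    return [sum(p[i] for p in points) / n for i in range(3)]


def oracle_hydrophobic(lig_carbons, rec_carbons, cfg):
    """All (ligand C, receptor C) pairs within the cutoff; no clustering."""
    out = set()
    for la in lig_carbons:
        for ra in rec_carbons:
            if _dist(la.coords, ra.coords) <= cfg.hydroph_dist_max:
                out.add((la.serial, ra.serial))
    return out


def oracle_hydrophobic_cluster(pairs):
    """Independent two-stage reduction of raw hydrophobic pairs.

    ``pairs`` is a list of (lig_atom, rec_atom, dist). Stage 1 keeps the
    closest pair per (ligand atom, receptor residue); stage 2 collapses
    fully connected contact clusters to their single closest contact.
    """
    stage1 = {}
    for la, ra, d in pairs:
        key = (la.serial, id(ra.parent))
        cur = stage1.get(key)
        if cur is None or (d, ra.serial, la.serial) < (cur[2], cur[1].serial,
                                                       cur[0].serial):
            stage1[key] = (la, ra, d)
    kept = list(stage1.values())
    # connected components by shared atoms
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        parent[find(x)] = find(y)

    for la, ra, _ in kept:
        union(("L", la.serial), ("R", ra.serial))
    comps = {}
    for la, ra, d in kept:
        comps.setdefault(find(("L", la.serial)), []).append((la, ra, d))
    out = set()
    for edges in comps.values():
        ligs = {la.serial for la, _, _ in edges}
        recs = {ra.serial for _, ra, _ in edges}
        if len(edges) == len(ligs) * len(recs) and len(edges) > 1:
            la, ra, d = min(edges, key=lambda e: (e[2], e[1].serial,
                                                  e[0].serial))
            out.add((la.serial, ra.serial))
        else:
            out.update((la.serial, ra.serial) for la, ra, _ in edges)
    return out


def oracle_hbonds(donors, acceptors, cfg):
    """(donor serial, acceptor serial) pairs satisfying distance + angle.

    ``donors`` is a list of (donor atom, [hydrogen atoms]).
    """
    out = set()
    for d_atom, hydrogens in donors:
        for a in acceptors:
            if a is d_atom:
                continue
            dd = _dist(d_atom.coords, a.coords)
            if dd > cfg.hbond_dist_max or dd < 1.5:
                continue
            if not hydrogens:
                out.add((d_atom.serial, a.serial))
                continue
            for h in hydrogens:
                if _angle_at(h.coords, d_atom.coords, a.coords) \
                        >= cfg.hbond_don_angle_min:
                    out.add((d_atom.serial, a.serial))
                    break
    return out


def oracle_water_bridges(lig_polar, rec_polar, waters, cfg):
    """(donor serial, acceptor serial, water serial) triples.

    ``lig_polar``/``rec_polar`` are lists of (atom, is_donor, is_acceptor).
    """
    out = set()
    for w in waters:
        for la, l_don, l_acc in lig_polar:
            for ra, r_don, r_acc in rec_polar:
                if la is ra:
                    continue
                dl = _dist(la.coords, w.coords)
                dr = _dist(ra.coords, w.coords)
                if not (cfg.water_bridge_mindist <= dl
                        <= cfg.water_bridge_maxdist):
                    continue
                if not (cfg.water_bridge_mindist <= dr
                        <= cfg.water_bridge_maxdist):
                    continue
                om = _angle_at(w.coords, la.coords, ra.coords)
                if not (cfg.water_bridge_omega_min <= om
                        <= cfg.water_bridge_omega_max):
                    continue
                if l_don and r_acc:
                    out.add((la.serial, ra.serial, w.serial))
                if r_don and l_acc:
                    out.add((ra.serial, la.serial, w.serial))
    return out


def oracle_salt_bridges(lig_charges, rec_charges, cfg):
    """Frozenset pairs of (pos atom serials, neg atom serials) within cutoff."""
    out = set()
    for lc in lig_charges:
        for rc in rec_charges:
            if lc.sign == rc.sign:
                continue
            if _dist(_mean([a.coords for a in lc.atoms]),
                     _mean([a.coords for a in rc.atoms])) \
                    <= cfg.saltbridge_dist_max:
                pos, neg = (lc, rc) if lc.sign == "positive" else (rc, lc)
                out.add((frozenset(a.serial for a in pos.atoms),
                         frozenset(a.serial for a in neg.atoms)))
    return out


def _plane_of(atoms):
    """Best-fit plane normal by Newell's method (independent of SVD)."""
    pts = [a.coords for a in atoms]
    n = len(pts)
    nx = ny = nz = 0.0
    for i in range(n):
        x1, y1, z1 = pts[i]
        x2, y2, z2 = pts[(i + 1) % n]
        nx += (y1 - y2) * (z1 + z2)
        ny += (z1 - z2) * (x1 + x2)
        nz += (x1 - x2) * (y1 + y2)
    length = math.sqrt(nx * nx + ny * ny + nz * nz)
    return _mean(pts), [nx / length, ny / length, nz / length]


def oracle_pistacking(lig_rings, rec_rings, cfg):
    """(lig ring serials, rec ring serials, type) without multi-ring dedup."""
    out = set()
    for lr in lig_rings:
        for rr in rec_rings:
            c1, n1 = _plane_of(lr.atoms)
            c2, n2 = _plane_of(rr.atoms)
            d = _dist(c1, c2)
            if d > cfg.pistack_dist_max:
                continue
            ang = _vec_angle(n1, n2)
            ang = min(ang, 180.0 - ang)
            if ang <= cfg.pistack_ang_dev:
                stype = "P"
            elif ang >= 90.0 - cfg.pistack_ang_dev:
                stype = "T"
            else:
                continue
            offs = []
            for c, nrm, other in ((c1, n1, c2), (c2, n2, c1)):
                dvec = _sub(other, c)
                proj = _dot(dvec, nrm)
                lateral = math.sqrt(max(_dot(dvec, dvec) - proj * proj, 0.0))
                offs.append(lateral)
            if min(offs) <= cfg.pistack_offset_max:
                out.add((frozenset(a.serial for a in lr.atoms),
                         frozenset(a.serial for a in rr.atoms), stype))
    return out


def oracle_pication(rings, charges, cfg):
    """(ring serials, charge serials) pairs; face-on rule for guanidinium."""
    out = set()
    for ring in rings:
        for ch in charges:
            if ch.sign != "positive":
                continue
            c1, n1 = _plane_of(ring.atoms)
            cc = _mean([a.coords for a in ch.atoms])
            if _dist(c1, cc) > cfg.pication_dist_max:
                continue
            if ch.label in ("guanidinium", "amidinium"):
                ang = _vec_angle(n1, _sub(cc, c1))
                ang = min(ang, 180.0 - ang)
                if ang > cfg.pication_face_angle_max:
                    continue
            out.add((frozenset(a.serial for a in ring.atoms),
                     frozenset(a.serial for a in ch.atoms)))
    return out


def oracle_halogen(donors, acceptors, cfg):
    """(halogen serial, acceptor serial) pairs.

    ``donors``: (halogen atom, carbon atom); ``acceptors``: (atom, y atom).
    """
    out = set()
    for x, c in donors:
        for a, y in acceptors:
            d = _dist(x.coords, a.coords)
            if d > cfg.halogen_dist_max:
                continue
            don = _angle_at(x.coords, c.coords, a.coords)
            if abs(don - cfg.halogen_don_angle) > cfg.halogen_don_angle_dev:
                continue
            acc = _angle_at(a.coords, y.coords, x.coords)
            if abs(acc - cfg.halogen_acc_angle) > cfg.halogen_acc_angle_dev:
                continue
            out.add((x.serial, a.serial))
    return out


def oracle_metal(metals, targets, cfg):
    """(metal serial, target serial) coordination pairs within the cutoff."""
    out = set()
    for m in metals:
        for t in targets:
            if t is m:
                continue
            if _dist(m.coords, t.coords) <= cfg.metal_dist_max:
                out.add((m.serial, t.serial))
    return out
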