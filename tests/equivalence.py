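"""Detector-vs-oracle equivalence harness over random micro-geometries."""

import numpy as np

import microgeo
import oracle
from nciprof.config import ThresholdConfig
from nciprof.detect import (_cluster_hydrophobic, detect_halogen_bonds,
                            detect_hbonds, detect_hydrophobic,
                            detect_metal_complexes, detect_pication,
                            detect_pistacking, detect_salt_bridges,
                            detect_water_bridges)

DETECTORS = ("hydrophobic", "hbond", "water_bridge", "salt_bridge",
             "pistack", "pication", "halogen", "metal")


def compare_one(detector: str, rng, cfg: ThresholdConfig) -> bool:
    """Run one random micro-geometry through detector and oracle; True when
    the reported pair sets are identical."""
    if detector == "hydrophobic":
        lig, rec = microgeo.gen_hydrophobic(rng)
        raw = detect_hydrophobic(lig, rec, cfg, refine=False)
        got = {(c.lig_atom.serial, c.rec_atom.serial) for c in raw}
        want = oracle.oracle_hydrophobic(
            [h.atom for h in lig.hydrophobics],
            [h.atom for h in rec.hydrophobics], cfg)
        if got != want:
            return False
        clustered = {(c.lig_atom.serial, c.rec_atom.serial)
                     for c in _cluster_hydrophobic(raw)}
        want_cl = oracle.oracle_hydrophobic_cluster(
            [(c.lig_atom, c.rec_atom, c.dist) for c in raw])
        return clustered == want_cl
    if detector == "hbond":
        lig, rec = microgeo.gen_hbond(rng)
        got = {(hb.donor.serial, hb.acceptor.serial)
               for hb in detect_hbonds(lig, rec, cfg)}
        want = oracle.oracle_hbonds(
            [(d.donor_atom, d.hydrogens) for d in lig.donors],
            [a.acceptor_atom for a in rec.acceptors], cfg)
        want |= oracle.oracle_hbonds(
            [(d.donor_atom, d.hydrogens) for d in rec.donors],
            [a.acceptor_atom for a in lig.acceptors], cfg)
        return got == want
    if detector == "water_bridge":
        lig, rec, waters, lig_polar, rec_polar = microgeo.gen_water_bridge(rng)
        got = {(wb.donor.serial, wb.acceptor.serial, wb.water_oxygen.serial)
               for wb in detect_water_bridges(lig, rec, waters, cfg)}
        want = oracle.oracle_water_bridges(
            lig_polar, rec_polar, [w.atom for w in waters], cfg)
        return got == want
    if detector == "salt_bridge":
        lig, rec, lig_ch, rec_ch = microgeo.gen_salt_bridge(rng)
        got = {(frozenset(a.serial for a in sb.pos_center.atoms),
                frozenset(a.serial for a in sb.neg_center.atoms))
               for sb in detect_salt_bridges(lig, rec, cfg)}
        want = oracle.oracle_salt_bridges(lig_ch, rec_ch, cfg)
        return got == want
    if detector == "pistack":
        lig, rec = microgeo.gen_pistack(rng)
        got = {(frozenset(a.serial for a in ps.lig_ring.atoms),
                frozenset(a.serial for a in ps.rec_ring.atoms),
                ps.stack_type)
               for ps in detect_pistacking(lig, rec, cfg, refine=False)}
        want = oracle.oracle_pistacking(lig.rings, rec.rings, cfg)
        return got == want
    if detector == "pication":
        lig, rec = microgeo.gen_pication(rng)
        got = {(frozenset(a.serial for a in pc.ring.atoms),
                frozenset(a.serial for a in pc.charge.atoms))
               for pc in detect_pication(lig, rec, cfg, refine=False)}
        want = oracle.oracle_pication(lig.rings, rec.pos_charges, cfg)
        return got == want
    if detector == "halogen":
        lig, rec, adjacency, acc_pairs = microgeo.gen_halogen(rng)
        got = {(xb.halogen.serial, xb.acceptor.serial)
               for xb in detect_halogen_bonds(lig, rec, cfg,
                                              adjacency=adjacency)}
        want = oracle.oracle_halogen(
            [(hd.halogen, hd.carbon) for hd in lig.halogen_donors],
            acc_pairs, cfg)
        return got == want
    if detector == "metal":
        lig, rec = microgeo.gen_metal(rng)
        got = {(mc.metal.serial, mc.target.serial)
               for mc in detect_metal_complexes(lig, rec, [], cfg)}
        want = oracle.oracle_metal(
            [m.atom for m in lig.metals],
            [a.acceptor_atom for a in rec.acceptors], cfg)
        return got == want
    raise ValueError(detector)


def run_equivalence(seed: int, trials: int = 200, cfg=None) -> dict:
    """``trials`` random micro-geometries per detector; returns per-detector
    (agreements, trials)."""
    cfg = cfg or ThresholdConfig()
    results = {}
    for i, detector in enumerate(DETECTORS):
        rng = np.random.default_rng(seed * 100 + i)
        ok = sum(compare_one(detector, rng, cfg) for _ in range(trials))
        results[detector] = (ok, trials)
    return results
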