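"""Serialisation of profiling results to parsable XML and flat text.

Ordering is total and deterministic: binding sites by ligand identifier
(chain, then sequence number), interactions by the fixed catalogue order,
then receptor residue, then distance. Distances and angles are fixed at two
decimals. The XML layout is described by the schema shipped with the
package (``data/report.xsd``).
"""

from __future__ import annotations

import re
from importlib import resources

from lxml import etree

from . import __version__
from .detect import INTERACTION_ORDER
from .profile import ProfileResult, SiteResult

__all__ = ["write_xml", "write_text", "summarize", "parse_text_counts",
           "parse_xml_counts", "write_reports", "load_schema"]


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.2f}"
    return str(value)


def _serials(atoms) -> str:
    return ",".join(str(a.serial) for a in atoms)


def _short_label(res) -> str:
    """Residue label in Name+Number form, e.g. PHE438."""
    return f"{res.name}{res.seq_number}{res.insertion_code}"


def _common_attrs(rec) -> dict:
    res = rec.rec_residue
    return {
        "rec_residue": _short_label(res),
        "rec_chain": res.chain_id,
        "receptor_is_nucleic": rec.receptor_is_nucleic,
    }


def _record_attrs(rec) -> dict:
    t = rec.itype
    a = _common_attrs(rec)
    if t == "hydrophobic":
        a.update(lig_serial=rec.lig_atom.serial, rec_serial=rec.rec_atom.serial,
                 dist=rec.dist)
    elif t == "hbond":
        a.update(donor_serial=rec.donor.serial,
                 acceptor_serial=rec.acceptor.serial,
                 donor_is_ligand=rec.donor_is_ligand, dist_da=rec.dist_da)
        if rec.dist_ha is not None:
            a["dist_ha"] = rec.dist_ha
        if rec.angle is not None:
            a["angle"] = rec.angle
        if rec.unverified:
            a["unverified"] = True
    elif t == "water_bridge":
        a.update(donor_serial=rec.donor.serial,
                 acceptor_serial=rec.acceptor.serial,
                 water_serial=rec.water_oxygen.serial,
                 water_residue=_short_label(rec.water_oxygen.parent),
                 dist_donor_water=rec.dist_donor_water,
                 dist_acceptor_water=rec.dist_acceptor_water,
                 omega=rec.omega, donor_is_ligand=rec.donor_is_ligand)
    elif t == "salt_bridge":
        a.update(pos_serials=_serials(rec.pos_center.atoms),
                 neg_serials=_serials(rec.neg_center.atoms),
                 pos_group=rec.pos_center.label or "positive",
                 neg_group=rec.neg_center.label or "negative",
                 pos_is_ligand=rec.pos_is_ligand, dist=rec.dist)
    elif t == "pistack":
        a.update(lig_serials=_serials(rec.lig_ring.atoms),
                 rec_serials=_serials(rec.rec_ring.atoms),
                 dist=rec.dist, angle=rec.angle, offset=rec.offset,
                 stack_type=rec.stack_type)
    elif t == "pication":
        a.update(ring_serials=_serials(rec.ring.atoms),
                 charge_serials=_serials(rec.charge.atoms),
                 ring_is_ligand=rec.ring_is_ligand, dist=rec.dist)
    elif t == "halogen":
        a.update(halogen_serial=rec.halogen.serial,
                 carbon_serial=rec.carbon.serial,
                 acceptor_serial=rec.acceptor.serial,
                 dist=rec.dist, don_angle=rec.don_angle,
                 acc_angle=rec.acc_angle)
    elif t == "metal":
        a.update(metal_serial=rec.metal.serial, target_serial=rec.target.serial,
                 dist=rec.dist, geometry=rec.geometry_label,
                 coordination_number=rec.coordination_number,
                 metal_is_ligand=rec.metal_is_ligand,
                 target_is_ligand=rec.target_is_ligand)
    return a


def _sorted_sites(result: ProfileResult) -> list:
    def key(sr: SiteResult):
        primary = sr.ligand.residues[0]
        return (primary.chain_id, primary.seq_number, primary.name)
    return sorted(result.sites, key=key)


def write_xml(result: ProfileResult) -> str:
    """Serialise a profiling result to the XML contract surface."""
    root = etree.Element("interaction_report", engine="nciprof",
                         version=__version__, input=str(result.input_name))
    config = etree.SubElement(root, "configuration")
    for k, v in result.config.to_dict().items():
        etree.SubElement(config, "threshold", key=k, value=_fmt(v))
    for k, v in result.mode.to_dict().items():
        etree.SubElement(config, "mode", key=k, value=_fmt(v))
    hyd = etree.SubElement(root, "hydrogenation",
                           added=str(result.hydrogenation.total_added),
                           failed=str(len(result.hydrogenation.failed)))
    for label, name in result.hydrogenation.failed:
        etree.SubElement(hyd, "placement_failure", residue=label, atom=name)
    sites_el = etree.SubElement(root, "binding_sites",
                                count=str(len(result.sites)))
    for sr in _sorted_sites(result):
        lig = sr.ligand
        site_el = etree.SubElement(
            sites_el, "binding_site", id=lig.identifier, ligand_kind=lig.kind,
            composite=_fmt(lig.composite),
            has_contacts=_fmt(not sr.site.is_empty))
        summary = sr.site.receptor_kind_summary
        etree.SubElement(site_el, "receptor_summary",
                         **{k: str(v) for k, v in summary.items()})
        for itype in INTERACTION_ORDER:
            records = sr.interactions.get(itype, [])
            group = etree.SubElement(site_el, "interaction_group",
                                     type=itype, count=str(len(records)))
            for rec in records:
                attrs = {k: _fmt(v) for k, v in _record_attrs(rec).items()}
                etree.SubElement(group, "interaction", type=itype, **attrs)
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


_TEXT_COLUMNS = {
    "hydrophobic": ("rec_residue", "rec_chain", "lig_serial", "rec_serial",
                    "dist"),
    "hbond": ("rec_residue", "rec_chain", "donor_serial", "acceptor_serial",
              "donor_is_ligand", "dist_da", "dist_ha", "angle", "unverified"),
    "water_bridge": ("rec_residue", "rec_chain", "water_residue",
                     "dist_donor_water", "dist_acceptor_water", "omega",
                     "donor_is_ligand"),
    "salt_bridge": ("rec_residue", "rec_chain", "pos_group", "neg_group",
                    "pos_is_ligand", "dist"),
    "pistack": ("rec_residue", "rec_chain", "stack_type", "dist", "angle",
                "offset"),
    "pication": ("rec_residue", "rec_chain", "ring_is_ligand", "dist"),
    "halogen": ("rec_residue", "rec_chain", "halogen_serial",
                "acceptor_serial", "dist", "don_angle", "acc_angle"),
    "metal": ("rec_residue", "rec_chain", "metal_serial", "target_serial",
              "dist", "geometry", "coordination_number"),
}


def write_text(result: ProfileResult) -> str:
    """Human-readable flat-text report with the same content as the XML."""
    lines = []
    lines.append(f"nciprof {__version__} interaction report")
    lines.append(f"input: {result.input_name}")
    lines.append("")
    lines.append("active thresholds:")
    for k, v in result.config.to_dict().items():
        lines.append(f"  {k} = {_fmt(v)}")
    lines.append("mode flags:")
    for k, v in result.mode.to_dict().items():
        lines.append(f"  {k} = {_fmt(v)}")
    lines.append(f"hydrogens added: {result.hydrogenation.total_added}"
                 f" (placement failures: {len(result.hydrogenation.failed)})")
    lines.append("")
    sites = _sorted_sites(result)
    if not sites:
        lines.append("no ligand binding sites found")
    for sr in sites:
        lig = sr.ligand
        lines.append("=" * 70)
        lines.append(f"binding site {lig.identifier} ({lig.kind})")
        summary = sr.site.receptor_kind_summary
        lines.append("receptor composition: " + ", ".join(
            f"{k}={v}" for k, v in summary.items()))
        if sr.site.is_empty:
            lines.append("no contacts")
        if sr.total == 0:
            lines.append("no interactions detected")
            lines.append("")
            continue
        for itype in INTERACTION_ORDER:
            records = sr.interactions.get(itype, [])
            if not records:
                continue
            lines.append("")
            lines.append(f"--- {itype} ({len(records)}) ---")
            cols = _TEXT_COLUMNS[itype]
            rows = []
            for rec in records:
                attrs = _record_attrs(rec)
                rows.append([_fmt(attrs.get(c, "-")) if attrs.get(c) is not None
                             else "-" for c in cols])
            widths = [max(len(c), *(len(r[i]) for r in rows))
                      for i, c in enumerate(cols)]
            lines.append("| " + " | ".join(
                c.ljust(widths[i]) for i, c in enumerate(cols)) + " |")
            for r in rows:
                lines.append("| " + " | ".join(
                    r[i].ljust(widths[i]) for i in range(len(cols))) + " |")
        lines.append("")
    return "\n".join(lines) + "\n"


def summarize(result: ProfileResult) -> dict:
    """Per-type interaction counts, plus counts keyed by receptor chain."""
    counts = {itype: 0 for itype in INTERACTION_ORDER}
    per_chain: dict = {}
    per_site: dict = {}
    for sr in _sorted_sites(result):
        site_counts = {itype: len(sr.interactions.get(itype, []))
                       for itype in INTERACTION_ORDER}
        per_site[sr.ligand.identifier] = site_counts
        for itype in INTERACTION_ORDER:
            counts[itype] += site_counts[itype]
            for rec in sr.interactions.get(itype, []):
                chain = rec.rec_residue.chain_id
                per_chain.setdefault(chain, {t: 0 for t in INTERACTION_ORDER})
                per_chain[chain][itype] += 1
    out = dict(counts)
    out["per_chain"] = per_chain
    out["per_site"] = per_site
    return out


_SECTION_RE = re.compile(r"^--- (\w+) \((\d+)\) ---$")


def parse_text_counts(text: str) -> dict:
    """Recover per-type interaction counts from a flat-text report (by
    counting table rows, not by trusting the section headers)."""
    counts = {itype: 0 for itype in INTERACTION_ORDER}
    current = None
    header_seen = False
    for line in text.splitlines():
        m = _SECTION_RE.match(line.strip())
        if m:
            current = m.group(1)
            header_seen = False
            continue
        if current and line.strip().startswith("|"):
            if not header_seen:
                header_seen = True  # column header row
            else:
                counts[current] += 1
        elif current and not line.strip():
            current = None
    return counts


def parse_xml_counts(xml_text: str) -> dict:
    root = etree.fromstring(xml_text.encode())
    counts = {itype: 0 for itype in INTERACTION_ORDER}
    for el in root.iter("interaction"):
        counts[el.get("type")] += 1
    return counts


def load_schema() -> etree.XMLSchema:
    """The XML schema the report contract is validated against."""
    data = (resources.files("nciprof") / "data" / "report.xsd").read_bytes()
    return etree.XMLSchema(etree.fromstring(data))


def write_reports(result: ProfileResult, outdir, formats=("xml", "txt"),
                  stem=None) -> list:
    """Write ``<stem>.report.{xml,txt}`` files; returns the paths written."""
    import os
    os.makedirs(outdir, exist_ok=True)
    if stem is None:
        base = os.path.basename(str(result.input_name))
        stem = base.rsplit(".", 1)[0] if "." in base else base
    written = []
    for fmt in formats:
        path = os.path.join(outdir, f"{stem}.report.{fmt}")
        content = write_xml(result) if fmt == "xml" else write_text(result)
        with open(path, "w") as fh:
            fh.write(content)
        written.append(path)
    return written
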