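"""Loader for the residue feature template table.

Templates name, per standard residue, the hydrogen-bond donors (with the
number of hydrogens each carries at pH 7), acceptors, charged groups and
aromatic rings. The table ships as versioned plain text so tests can diff it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = ["ResidueTemplate", "get_template", "load_templates"]


@dataclass
class ResidueTemplate:
    residue: str
    donors: dict = field(default_factory=dict)       # atom name -> n hydrogens
    acceptors: list = field(default_factory=list)    # atom names
    pos_charges: list = field(default_factory=list)  # (atom names, label)
    pos_charges_conditional: list = field(default_factory=list)
    neg_charges: list = field(default_factory=list)
    rings: list = field(default_factory=list)        # lists of atom names


@lru_cache(maxsize=1)
def load_templates() -> dict:
    text = (resources.files("nciprof") / "data" / "residue_templates.tsv").read_text()
    templates: dict = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        resname, feature, atoms = parts[0], parts[1], parts[2]
        param = parts[3] if len(parts) > 3 else ""
        tpl = templates.setdefault(resname, ResidueTemplate(resname))
        names = [a.strip() for a in atoms.split(",")]
        if feature == "donor":
            tpl.donors[names[0]] = int(param)
        elif feature == "acceptor":
            tpl.acceptors.append(names[0])
        elif feature == "pos_charge":
            tpl.pos_charges.append((names, param))
        elif feature == "pos_charge_conditional":
            tpl.pos_charges_conditional.append((names, param))
        elif feature == "neg_charge":
            tpl.neg_charges.append((names, param))
        elif feature == "ring":
            tpl.rings.append(names)
        else:
            raise ValueError(f"unknown template feature {feature!r}")
    return templates


def get_template(resname: str):
    """Template for a residue name, or None when no template is defined."""
    return load_templates().get(resname.strip().upper())
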