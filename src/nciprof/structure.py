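"""Coordinate/topology data model for PDB-format macromolecular structures.

The parser keeps exactly what the geometric interaction rules downstream
need: one model's worth of atoms with elements and coordinates, residues
classified by kind (amino acid, DNA, RNA, water, metal ion, other hetero),
and the CONECT adjacency list used later for ligand bond perception.
Nucleic residues are recognised purely by name: U/A/C/G for RNA and
DT/DA/DC/DG for DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "parse_pdb",
    "select_model",
    "write_pdb",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
DNA_NAMES = {"DT", "DA", "DC", "DG"}
RNA_NAMES = {"U", "A", "C", "G"}
WATER_NAMES = {"HOH", "WAT", "DOD"}

#: default metal list; extendable through ThresholdConfig.metal_symbols
METAL_SYMBOLS = {"NA", "K", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD"}

# elements that may legitimately appear in biomolecular PDB files; used for
# element inference when columns 77-78 are blank
_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CO", "NI", "CU", "CD",
    "SE", "SI", "AL", "LI", "BE", "AS", "AG", "AU", "HG", "PB", "PT", "RB",
    "CS", "SR", "BA", "TI", "CR", "MO",
}
_ONE_LETTER_ELEMENTS = {"H", "C", "N", "O", "F", "P", "S", "K", "I", "B", "D"}

_VALID_ELEMENTS = _TWO_LETTER_ELEMENTS | _ONE_LETTER_ELEMENTS


class PDBParseError(ValueError):
    """Raised when PDB input cannot be turned into a Structure.

    Carries the 1-based line number and content of the first offending line.
    """

    def __init__(self, message: str, line_number: Optional[int] = None,
                 line: Optional[str] = None):
        self.line_number = line_number
        self.line = line
        if line_number is not None:
            message = f"{message} (line {line_number}: {line!r})"
        super().__init__(message)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False
    parent: Optional["Residue"] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coords - other.coords))

    def __repr__(self):
        res = self.parent.label if self.parent is not None else "?"
        return f"<Atom {self.serial} {self.name} ({self.element}) of {res}>"

    # dataclass eq would compare arrays; identity semantics are what the
    # detectors need (atoms live in exactly one structure)
    __hash__ = object.__hash__
    __eq__ = object.__eq__


def classify_residue(name: str, atoms: Optional[Iterable[Atom]] = None) -> str:
    """Residue-kind classification, a pure function of the residue name.

    A single-atom residue whose element is in the metal list is a metal ion;
    that is the only case where atom content participates.
    """
    name = name.strip().upper()
    if name in DNA_NAMES:
        return "dna"
    if name in RNA_NAMES:
        return "rna"
    if name in WATER_NAMES:
        return "water"
    if name in AMINO_ACIDS:
        return "amino_acid"
    if atoms is not None:
        atoms = list(atoms)
        if len(atoms) == 1 and atoms[0].element in METAL_SYMBOLS:
            return "metal_ion"
    return "other_hetero"


@dataclass
class Residue:
    name: str
    seq_number: int
    insertion_code: str
    chain_id: str
    atoms: list = field(default_factory=list)
    kind: str = "other_hetero"

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_number, self.insertion_code, self.name)

    @property
    def label(self) -> str:
        """Human-readable residue label, e.g. ``PHE438`` or ``DG7``."""
        chain = self.chain_id if self.chain_id.strip() else "_"
        icode = self.insertion_code.strip()
        return f"{self.name}{self.seq_number}{icode}.{chain}"

    @property
    def is_nucleic(self) -> bool:
        return self.kind in ("dna", "rna")

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if a.is_heavy]

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self):
        return f"<Residue {self.label} kind={self.kind} natoms={len(self.atoms)}>"

    __hash__ = object.__hash__
    __eq__ = object.__eq__


class Structure:
    """A parsed PDB structure: ordered models of chains of residues.

    All atom-yielding accessors are restricted to ``selected_model``
    (1-based, following MODEL record numbering).
    """

    def __init__(self, models: list, header_id: Optional[str] = None,
                 conect: Optional[dict] = None):
        if not models:
            raise ValueError("structure needs at least one model")
        #: list of models; each model is an ordered list of Residue
        self.models = models
        self.header_id = header_id
        #: serial -> set of serials bonded per CONECT records
        self.conect = conect or {}
        self.selected_model = 1

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self) -> list:
        return list(self.models[self.selected_model - 1])

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def heavy_atoms(self) -> Iterator[Atom]:
        for a in self.atoms():
            if a.is_heavy:
                yield a

    def chains(self) -> list:
        seen = []
        for res in self.residues():
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def atom_by_serial(self, serial: int) -> Optional[Atom]:
        for a in self.atoms():
            if a.serial == serial:
                return a
        return None

    def __repr__(self):
        return (f"<Structure models={self.n_models} selected={self.selected_model} "
                f"residues={len(self.residues())}>")


def _infer_element(atom_name: str, resname: str, is_hetero: bool) -> str:
    """Infer the element when columns 77-78 are blank.

    Digits are stripped; leading characters are matched against element
    symbols with two-letter symbols preferred for metals. For ATOM records of
    standard residues the first alphabetic character wins (so CA is a carbon
    in alanine but calcium as a lone HETATM).
    """
    raw = atom_name.strip().upper()
    stripped = "".join(c for c in raw if not c.isdigit())
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    resname = resname.strip().upper()
    standard = resname in AMINO_ACIDS or resname in DNA_NAMES or resname in RNA_NAMES
    if not standard:
        two = stripped[:2]
        if two in _TWO_LETTER_ELEMENTS and (is_hetero or atom_name[:1].strip()):
            return two
    one = stripped[0]
    if one == "D":
        return "H"
    if one in _ONE_LETTER_ELEMENTS:
        return one
    two = stripped[:2]
    if two in _TWO_LETTER_ELEMENTS:
        return two
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _parse_coord_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "_"
        seq = int(line[22:26])
        icode = line[26].strip() if len(line) > 26 else ""
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError) as exc:
        raise PDBParseError("malformed coordinate record", lineno, line.rstrip("\n")) from exc
    element = line[76:78].strip().upper() if len(line) >= 77 else ""
    is_hetero = line.startswith("HETATM")
    if element == "D":
        element = "H"
    if element not in _VALID_ELEMENTS:
        try:
            element = _infer_element(line[12:16], resname, is_hetero)
        except ValueError as exc:
            raise PDBParseError(str(exc), lineno, line.rstrip("\n")) from exc
    return {
        "serial": serial, "name": name, "altloc": altloc, "resname": resname,
        "chain": chain, "seq": seq, "icode": icode,
        "coords": (x, y, z), "occupancy": occupancy,
        "element": element, "is_hetero": is_hetero,
    }


def parse_pdb(source) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    ``source`` is a string, an open text stream, or a path-like. All
    ATOM/HETATM records of all MODEL blocks are captured; CONECT records are
    retained as an adjacency list. For atoms with alternate locations, the
    highest-occupancy altloc per atom name is kept (ties broken toward
    altloc ``A``, then first encountered).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and (text.endswith(".pdb") or text.endswith(".ent")):
            with open(text) as fh:
                text = fh.read()
    if not text.strip():
        raise PDBParseError("empty PDB input")

    header_id = None
    conect: dict = {}
    models_raw: list = []
    current: list = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "HEADER":
            tail = line[62:66].strip()
            if len(tail) == 4:
                header_id = tail
        elif rec.startswith("MODEL"):
            if current:
                models_raw.append(current)
            current = []
        elif rec == "ENDMDL":
            models_raw.append(current)
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_coord_line(line, lineno))
        elif rec == "CONECT":
            fields = [line[i:i + 5].strip() for i in range(6, min(len(line), 31), 5)]
            nums = [int(f) for f in fields if f]
            if nums:
                base = nums[0]
                for other in nums[1:]:
                    conect.setdefault(base, set()).add(other)
                    conect.setdefault(other, set()).add(base)
        # TER/END: residue boundaries are keyed explicitly, nothing to do

    if current:
        models_raw.append(current)
    models_raw = [m for m in models_raw if m]
    if not models_raw:
        raise PDBParseError("no parsable ATOM/HETATM records found")

    models = [_build_model(recs) for recs in models_raw]
    return Structure(models, header_id=header_id, conect=conect)


def _build_model(records: list) -> list:
    # group by residue key, preserving encounter order
    residues: dict = {}
    order: list = []
    for rec in records:
        key = (rec["chain"], rec["seq"], rec["icode"], rec["resname"])
        if key not in residues:
            residues[key] = []
            order.append(key)
        residues[key].append(rec)

    model = []
    for key in order:
        chain, seq, icode, resname = key
        recs = residues[key]
        # altloc resolution: per atom name keep highest occupancy
        by_name: dict = {}
        for rec in recs:
            prev = by_name.get(rec["name"])
            if prev is None:
                by_name[rec["name"]] = rec
            else:
                if rec["occupancy"] > prev["occupancy"] or (
                        rec["occupancy"] == prev["occupancy"]
                        and rec["altloc"] == "A" and prev["altloc"] != "A"):
                    by_name[rec["name"]] = rec
        res = Residue(name=resname, seq_number=seq, insertion_code=icode,
                      chain_id=chain)
        kept_names = set(by_name)
        for rec in recs:
            if by_name.get(rec["name"]) is not rec:
                continue
            kept_names.discard(rec["name"])
            atom = Atom(serial=rec["serial"], name=rec["name"],
                        element=rec["element"], coords=rec["coords"],
                        altloc=rec["altloc"], occupancy=rec["occupancy"],
                        is_hetero=rec["is_hetero"], parent=res)
            res.atoms.append(atom)
        res.kind = classify_residue(resname, res.atoms)
        model.append(res)
    return model


def select_model(structure: Structure, index: int) -> Structure:
    """Restrict all atom-yielding accessors to one MODEL (1-based)."""
    if not (1 <= index <= structure.n_models):
        available = ", ".join(str(i) for i in range(1, structure.n_models + 1))
        raise ValueError(
            f"model {index} does not exist; available models: {available}")
    structure.selected_model = index
    return structure


def write_pdb(structure: Structure, include_conect: bool = True) -> str:
    """Serialise the selected model back to PDB text (3-decimal coordinates)."""
    lines = []
    if structure.header_id:
        lines.append(f"HEADER    {'':40s}{'':11s}{structure.header_id}")
    for res in structure.residues():
        for a in res.atoms:
            rec = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name
            if len(name) < 4 and len(a.element) == 1:
                name = f" {name}"
            chain = res.chain_id if res.chain_id != "_" else " "
            lines.append(
                f"{rec}{a.serial:5d} {name:<4s}{a.altloc or ' ':1s}"
                f"{res.name:<3s} {chain:1s}{res.seq_number:4d}"
                f"{res.insertion_code or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}")
    if include_conect:
        for serial in sorted(structure.conect):
            partners = sorted(structure.conect[serial])
            for i in range(0, len(partners), 4):
                chunk = partners[i:i + 4]
                lines.append("CONECT" + f"{serial:5d}" +
                             "".join(f"{p:5d}" for p in chunk))
    lines.append("END")
    return "\n".join(lines) + "\n"
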