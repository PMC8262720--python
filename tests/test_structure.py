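"""PDB parsing, model selection and the structure data model."""

import numpy as np
import pytest

from nciprof.fixtures import multimodel_fixture, standard_suite
from nciprof.structure import (AMINO_ACIDS, PDBParseError, classify_residue,
                               parse_pdb, select_model, write_pdb)

ALA_LINE = ("ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
            "  1.00  0.00           C")


def test_single_record_identity():
    s = parse_pdb(ALA_LINE)
    assert s.n_models == 1
    residues = s.residues()
    assert len(residues) == 1
    res = residues[0]
    assert res.kind == "amino_acid"
    assert res.name == "ALA"
    atom = res.atoms[0]
    assert atom.element == "C"
    assert not atom.is_hetero
    assert np.allclose(atom.coords, [1.0, 2.0, 3.0])


def test_nucleic_residue_detected_by_name_even_as_atom_record():
    """DG written as plain ATOM records is still a DNA residue: the
    nucleic rule is purely name-based."""
    line = ("ATOM      1  N9  DG  B   7       0.000   0.000   0.000"
            "  1.00  0.00           N")
    res = parse_pdb(line).residues()[0]
    assert res.kind == "dna"


@pytest.mark.parametrize("name,kind", [
    ("DT", "dna"), ("DA", "dna"), ("DC", "dna"), ("DG", "dna"),
    ("U", "rna"), ("A", "rna"), ("C", "rna"), ("G", "rna"),
    ("HOH", "water"), ("WAT", "water"), ("DOD", "water"),
    ("ATP", "other_hetero"), ("XYZ", "other_hetero"),
] + [(aa, "amino_acid") for aa in sorted(AMINO_ACIDS)])
def test_residue_kind_is_pure_function_of_name(name, kind):
    assert classify_residue(name) == kind


@pytest.mark.parametrize("bad", ["", "   \n  \n", "REMARK nothing here\n"])
def test_empty_or_recordless_input_is_an_error(bad):
    with pytest.raises(PDBParseError):
        parse_pdb(bad)


def test_malformed_record_reports_line_number():
    text = ALA_LINE + "\nATOM      2  CB  ALA A   1     garbage here\n"
    with pytest.raises(PDBParseError) as exc:
        parse_pdb(text)
    assert exc.value.line_number == 2


def test_multimodel_roundtrip_against_manifest():
    text, man = multimodel_fixture(n_models=2)
    s = parse_pdb(text)
    assert s.n_models == 2
    counts = [sum(len(r.atoms) for r in m) for m in s.models]
    assert counts == man.atom_counts
    # model selection restricts accessors to that model's coordinates
    select_model(s, 2)
    coords_m2 = {a.serial: tuple(a.coords) for a in s.atoms()}
    select_model(s, 1)
    coords_m1 = {a.serial: tuple(a.coords) for a in s.atoms()}
    assert set(coords_m1) == set(coords_m2)
    assert any(coords_m1[k] != coords_m2[k] for k in coords_m1)


def test_select_model_out_of_range_lists_available():
    s = parse_pdb(ALA_LINE)
    assert select_model(s, 1) is s
    with pytest.raises(ValueError, match="available models: 1"):
        select_model(s, 3)


def test_altloc_keeps_highest_occupancy_then_a():
    text = "\n".join([
        "ATOM      1  CA AALA A   1       1.000   0.000   0.000"
        "  0.40  0.00           C",
        "ATOM      2  CA BALA A   1       2.000   0.000   0.000"
        "  0.60  0.00           C",
        "ATOM      3  CB AALA A   1       0.000   1.000   0.000"
        "  0.50  0.00           C",
        "ATOM      4  CB BALA A   1       0.000   2.000   0.000"
        "  0.50  0.00           C",
    ])
    res = parse_pdb(text).residues()[0]
    ca = res.get_atom("CA")
    cb = res.get_atom("CB")
    assert ca.coords[0] == 2.0          # higher occupancy wins
    assert cb.altloc == "A"             # tie broken toward altloc A
    assert len(res.atoms) == 2


@pytest.mark.parametrize("line,element", [
    # element columns present
    (ALA_LINE, "C"),
    # blank element columns: infer from the atom name
    ("ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00",
     "C"),
    ("HETATM    1 CA    CA A   1       0.000   0.000   0.000  1.00  0.00",
     "CA"),
    ("HETATM    1 FE    FE A   1       0.000   0.000   0.000  1.00  0.00",
     "FE"),
    ("HETATM    1 ZN    ZN A   1       0.000   0.000   0.000  1.00  0.00",
     "ZN"),
    ("ATOM      1  OG1 THR A   1       0.000   0.000   0.000  1.00  0.00",
     "O"),
])
def test_element_inference(line, element):
    atom = parse_pdb(line).residues()[0].atoms[0]
    assert atom.element == element


def test_conect_records_become_adjacency():
    text = "\n".join([
        "HETATM    1  C1  LIG L   1       0.000   0.000   0.000"
        "  1.00  0.00           C",
        "HETATM    2  O1  LIG L   1       3.000   0.000   0.000"
        "  1.00  0.00           O",
        "CONECT    1    2",
    ])
    s = parse_pdb(text)
    assert s.conect == {1: {2}, 2: {1}}


def test_roundtrip_preserves_atoms_and_coordinates():
    """Parsing then re-serialising preserves atom count, ordering and
    coordinates to PDB 3-decimal precision, for every suite fixture."""
    for name, text, _ in standard_suite():
        s = parse_pdb(text)
        s2 = parse_pdb(write_pdb(s))
        a1 = list(s.atoms())
        a2 = list(s2.atoms())
        assert len(a1) == len(a2), name
        for x, y in zip(a1, a2):
            assert x.serial == y.serial and x.name == y.name
            assert np.allclose(x.coords, y.coords, atol=5e-4)


def test_agrees_with_gemmi_on_fixture():
    """Independent parser cross-check: atom count and coordinates match
    gemmi's reading of the same file."""
    gemmi = pytest.importorskip("gemmi")
    name, text, _ = standard_suite()[0]
    ours = parse_pdb(text)
    theirs = gemmi.read_pdb_string(text)
    g_atoms = [a for model in theirs for chain in model
               for res in chain for a in res]
    o_atoms = list(ours.atoms())
    assert len(o_atoms) == len(g_atoms)
    for oa, ga in zip(o_atoms, g_atoms):
        assert oa.element.capitalize() == ga.element.name
        assert np.allclose(oa.coords, [ga.pos.x, ga.pos.y, ga.pos.z],
                           atol=1e-6)
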