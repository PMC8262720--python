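# nciprof

Rule-based profiling of non-covalent interactions between ligands and
macromolecular receptors — protein, DNA, RNA, or mixed complexes — from
PDB-format structures.

## The problem

Most deposited structures contain bound ligands, and understanding *how* a
ligand binds means enumerating the specific non-covalent contacts holding it
in place. `nciprof` detects eight interaction classes between a ligand and
its binding site:

hydrogen bonds, hydrophobic contacts, π-stacking, π-cation interactions,
salt bridges, water bridges, metal complexes and halogen bonds.

Beyond classic protein–small-molecule profiling, the engine treats nucleic
acids as first-class binding partners: a DNA duplex can be the receptor of
an intercalating drug, an RNA chain can be the ligand of an RNA-binding
protein, and a nucleotide triphosphate can contact protein, DNA and RNA
strands simultaneously in one site. RNA and DNA residues are recognised
purely by residue name (`U A C G` and `DT DA DC DG`) and assigned to the
receptor or to ligand candidacy by an analysis-mode flag.

The intended users are structural bioinformaticians profiling deposited
complexes or docking poses, in scripts (the `nciprof` Python API) or
pipelines (the `nciprof` CLI with machine-readable XML output).

## Method

Profiling runs in four stages:

1. **Structure preparation** — fixed-width PDB parsing into an explicit
   atom/residue/model data model (altlocs resolved to the highest-occupancy
   conformer, CONECT records kept as an adjacency list), model selection for
   multi-model entries, and hydrogenation: every polar donor (N/O/S)
   receives explicit hydrogens, either kept from the input or placed by
   idealised sp²/sp³ rules.
2. **Receptor/ligand splitting** — hetero residues not on the
   solvent/buffer exclusion list become ligand entities; covalently linked
   hetero residues merge into composites; each contiguous nucleic chain
   becomes one nucleic-chain ligand unless nucleic-receptor mode claims it
   for the receptor. The binding site is every receptor residue with a heavy
   atom within 7.5 Å of the ligand.
3. **Functional characterisation** — hydrogen-bond donors/acceptors,
   charged centres, aromatic rings, hydrophobic carbons, halogen-bond
   donors, metals and waters, perceived from residue-name templates for
   standard amino acids and nucleotides and from element/valence/
   functional-group rules on the bond graph for arbitrary ligands.
4. **Rule-based matching and filtering** — one geometric detector per
   interaction class, followed by deterministic refinement (hydrophobic
   contact clustering, suppression of hydrogen bonds subsumed by a salt
   bridge, of water bridges duplicating a direct hydrogen bond, and of
   duplicate purine multi-ring stacks).

All cutoffs are inclusive (≤/≥) and user-adjustable. The defaults:

| rule | default |
| --- | --- |
| hydrophobic C···C | ≤ 4.0 Å |
| H-bond D···A, ∠D–H···A | ≤ 4.1 Å, ≥ 100° |
| π-stack centroid distance, plane angle, offset | ≤ 5.5 Å, ≤ 30° of 0°/90°, ≤ 2.0 Å |
| π-cation centroid distance | ≤ 6.0 Å (face-on ≤ 30° for guanidinium) |
| salt bridge centroid distance | ≤ 5.5 Å |
| halogen X···A, ∠C–X···A, ∠Y–A···X | ≤ 4.0 Å, 165° ± 30°, 120° ± 30° |
| water bridge legs, ω at water | 2.5–4.1 Å, 75–140° |
| metal coordination | ≤ 3.0 Å |
| binding-site shell | 7.5 Å |

## Worked example

The package ships a synthetic-fixture generator used throughout the test
suite. One of its fixtures is a small RNA-binding-protein-like complex: a
five-residue RNA chain (UGGUG) bound by a phenylalanine stacking the second
guanine, an arginine under the same base, and a lysine reaching the third
residue's phosphate:

```bash
python -c "
from nciprof.fixtures import nucleic_complex_fixture
open('rna_complex.pdb', 'w').write(nucleic_complex_fixture()[0])"
nciprof rna_complex.pdb --out reports --format txt
```

The text report ends with:

```
binding site U:R:1 (nucleic_chain)
receptor composition: amino_acid=3, dna=0, rna=0, other=0

--- salt_bridge (1) ---
| rec_residue | rec_chain | pos_group | neg_group | pos_is_ligand | dist |
| LYS103      | A         | ammonium  | phosphate | false         | 4.00 |

--- pistack (1) ---
| rec_residue | rec_chain | stack_type | dist | angle | offset |
| PHE101      | A         | P          | 3.80 | 0.00  | 0.00   |

--- pication (1) ---
| rec_residue | rec_chain | ring_is_ligand | dist |
| ARG102      | A         | true           | 4.00 |
```

Read: the whole RNA chain is one ligand entity (`U:R:1`, kind
`nucleic_chain`); its binding site holds three protein residues; the engine
found one parallel (`P`) π-stack at 3.80 Å centroid distance, one π-cation
contact at 4.00 Å, and one salt bridge between the lysine ammonium and the
phosphate group at 4.00 Å — exactly the three contacts the generator
planted, with the NZ→phosphate-oxygen hydrogen bonds correctly subsumed by
the ionic record. With `--nucleic-receptor` the same RNA residues move into
the receptor instead and no nucleic ligand entity is formed.

Useful CLI flags: `--model N` (multi-model structures),
`--set KEY=VALUE` (any threshold or mode flag), `--config FILE`,
`--format xml,txt`, `--intra-chain/--no-intra-chain`,
`--modified-as-ligand`. Exit codes: 0 success, 2 usage, 3 parse error,
4 configuration error.

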