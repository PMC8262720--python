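# Methods

This note documents the models and procedural choices behind `nciprof`:
what each pipeline stage assumes, which parameters matter, what the
synthetic fixture generator does and does not emulate, and where the design
was genuinely open.

## Structure model

The parser reads fixed-width PDB records directly. Choices:

- **Models.** MODEL/ENDMDL blocks are kept as separate coordinate sets;
  exactly one model (default: the first) is visible to all downstream
  stages. Model indices are 1-based, matching MODEL record numbering.
- **Altlocs.** For each atom name within a residue the highest-occupancy
  alternate location is kept; ties break toward altloc `A`, then first
  encountered. Rationale: every geometric rule needs a single unambiguous
  conformer.
- **Elements.** Columns 77–78 when present; otherwise inferred from the
  atom name with digits stripped and two-letter symbols preferred for
  metals (`FE`, `ZN`, `MG`, …). For atoms of standard residues the
  one-letter reading wins, so `CA` is an α-carbon inside alanine but
  calcium as a lone HETATM.
- **Residue kinds** are a pure function of the residue name: `DT DA DC DG`
  → DNA, `U A C G` → RNA, `HOH WAT DOD` → water, the twenty standard codes
  → amino acid; a single-atom residue whose element is in the metal list is
  a metal ion; everything else is generic hetero. Blank chain identifiers
  are normalised to `_`.
- **CONECT** records are retained as a serial-number adjacency list and
  merged with distance-based bond perception (covalent radii + 0.45 Å
  tolerance, metals excluded) for ligand topology.

Malformed coordinate records and inputs without any ATOM/HETATM record
raise a structured parse error carrying the first offending line number.

## Hydrogenation

Hydrogen-bond donor angles need explicit hydrogen positions, but many
crystal structures carry none. `ensure_hydrogens` guarantees the donor
inventory:

- hydrogens present in the input are kept unmodified, including misplaced
  ones — the operation never moves an existing atom;
- missing hydrogens are placed by idealised rules: anti to the mean of the
  existing bond vectors when ≥ 2 neighbours fix the direction; trigonal
  in-plane pairs for sp² –NH₂ (amide, guanidinium, exocyclic base amines);
  staggered tetrahedral triplets for –NH₃⁺; water gets two hydrogens at
  0.96 Å and 104.5°. Rotatable hydroxyl/water hydrogens are oriented toward
  the nearest polar atom within 4 Å — a cheap deterministic stand-in for
  torsional optimisation that makes planted fixture geometries behave like
  optimised ones;
- bond lengths: N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å;
- histidine defaults to the neutral NE2-protonated tautomer; ND1 stays an
  acceptor. A histidine is treated as cationic only when both ring
  nitrogens carry hydrogens (e.g. supplied in the input).

A donor whose geometry prevents placement is recorded in the hydrogenation
report; the hydrogen-bond detector then evaluates it distance-only and
flags resulting bonds `unverified` rather than dropping them.

The operation is idempotent: a second call adds nothing.

## Protonation and feature perception

pH 7 conventions throughout: Asp/Glu deprotonated, Arg/Lys protonated,
nucleotide phosphates anionic. Standard residues use name-based templates
shipped as versioned plain text (`data/residue_templates.tsv`). Nucleotides
additionally get, in code, the `OP1/OP2` negative centre and acceptors, the
`O4'` acceptor, and for RNA the `O2'` donor+acceptor; purine bases
contribute the 6-ring, the 5-ring, and a fused-ring composite centroid so
stacking can be evaluated against all three representations (the
best-offset one is reported once).

Arbitrary ligands are perceived from the bond graph:

- donors/acceptors by element and heavy valence, with the carbonyl/hydroxyl
  distinction made from the C–O bond length (≤ 1.30 Å → carbonyl);
- charged groups by functional-group rules: carboxylate, phosphate,
  sulfate (≥ 2 terminal oxygens on the central atom), guanidinium and
  amidinium, quaternary nitrogen, and aliphatic amines (assumed protonated);
  a quaternary or protonated nitrogen is never an acceptor;
- rings by minimum-cycle-basis perception (networkx), accepted as aromatic
  when 5- or 6-membered over C/N/O/S, planar (RMSD from the best-fit plane
  ≤ 0.25 Å) and with every ring bond ≤ 1.45 Å. The bond-length criterion is
  what rejects saturated rings — an ideal cyclohexane chair has a planarity
  RMSD of exactly 0.25 Å, right at the threshold, and ribose puckers are
  borderline too, while sp²/aromatic bonds (≤ ~1.40 Å) sit clearly below
  1.45 Å and sp³ C–C bonds (~1.54 Å) clearly above. Fused aromatic rings
  sharing ≥ 2 atoms form one ring system with a composite centroid;
- hydrophobic atoms by one definitional rule everywhere: a carbon whose
  bonded heavy neighbours are all carbon;
- halogen-bond donors as carbon-bound Cl/Br/I; fluorine's σ-hole is weak,
  so F counts only when `fluorine_as_donor` is enabled.

Modified residues without a template fall back to the generic graph rules
with a logged warning — a fallback, not a claim of equivalence to curated
templates.

## Detection rules

All thresholds are inclusive and live in `ThresholdConfig` (Å, degrees).
Angle conventions: unsigned; ring-plane angles folded into [0°, 90°], so
ring normal sign never matters. Distances are Euclidean between atom
centres, or between unweighted group centroids for group rules.

- **Hydrophobic**: C···C pairs ≤ 4.0 Å, then two-stage clustering — per
  (ligand atom, receptor residue) keep the closest pair; fully connected
  contact clusters collapse to their single closest contact. Ties break by
  smallest distance, then lowest (receptor serial, ligand serial).
- **Hydrogen bond**: D···A ≤ 4.1 Å and ∠D–H···A ≥ 100° for some hydrogen on
  the donor; both directions evaluated; D···A pairs below 1.5 Å are
  ignored as covalent artefacts.
- **Water bridge**: ligand polar atom and receptor polar atom each within
  2.5–4.1 Å of the same water oxygen, donor/acceptor roles complementary,
  and the polar–O(water)–polar angle ω in 75–140°.
- **Salt bridge**: opposite-sign charged-centre centroids ≤ 5.5 Å;
  nucleotide phosphates are eligible negative partners.
- **π-stacking**: centroid distance ≤ 5.5 Å, interplanar angle within 30°
  of 0° (parallel, `P`) or 90° (T-shaped, `T`), lateral offset (minimum of
  the two in-plane projections) ≤ 2.0 Å.
- **π-cation**: ring centroid to charge centroid ≤ 6.0 Å; guanidinium and
  amidinium cations must approach face-on (ring normal vs centroid→cation
  ≤ 30°), since their in-plane approach is a hydrogen-bonding, not a
  cation–π, geometry.
- **Halogen bond**: X···A ≤ 4.0 Å, donor angle C–X···A within 165° ± 30°,
  acceptor angle Y–A···X within 120° ± 30°, where Y is the acceptor's bound
  heavy atom (lowest serial when several).
- **Metal complex**: metal–target (O/N/S or water O) ≤ 3.0 Å. The full
  coordination sphere is collected per metal — including receptor-internal
  partners, which provide context but are only reported when the ligand is
  involved — and labelled with the idealised geometry (linear, trigonal
  planar, tetrahedral, square planar, trigonal bipyramidal, square
  pyramidal, octahedral) minimising the RMSD between sorted observed and
  template pairwise angles; spheres of one partner are
  `other/underdetermined`.

These defaults match the published defaults of the reference interaction
profiling engine so results on real complexes are comparable; every value
is overridable per run.

### Refinement

Applied deterministically after raw detection: (a) hydrophobic clustering
as above; (b) a water bridge is dropped when the same ligand-atom/
receptor-atom pair forms a direct hydrogen bond; (c) hydrogen bonds
between member atoms of two salt-bridged groups are subsumed by the ionic
record; (d) purine/fused-system multi-ring stacks keep one best-offset
record per ring-system pair; (e) a salt bridge duplicating a π-cation
contact over the same centroids is dropped. The refinement order is this
package's own contract, validated by its oracles, and every surviving
record is re-audited against the active thresholds after each run.

## Synthetic fixtures: what they do and do not show

The generator plants minimal chemical groups (methanol donors, glycine
carbonyl acceptors, acetate/lysine ion pairs, pyrazine/benzene/phenyl
rings, a constructed guanine with idealised fused-ring geometry, phosphate
groups, water, Mg²⁺ with octahedral water spheres, halobenzenes) at exact
requested geometries, 40 Å apart per planted unit, and writes both the PDB
file and a manifest of expected interactions *computed from the file's own
3-decimal coordinates* by applying the inclusive rules directly. That makes
manifests exact even at thresholds; at-boundary fixtures use
lattice-exact constructions (e.g. the (0.9, 4.0) right triangle for an
exact 4.1 Å water-bridge leg) so quantisation cannot tip them over.
Optional seeded jitter (≤ 0.05 Å per coordinate) tests robustness; the
manifest recomputes expectations from the jittered coordinates, including
re-checking that generated rings still satisfy the aromaticity definition.

What passing the fixture suite shows: the detectors implement exactly the
stated geometric rules, including boundary and refinement behaviour, and
the whole pipeline (parse → hydrogenate → split → perceive → detect →
report) is exact on inputs whose ground truth is known by construction.

What it does not show: correctness of chemical *perception* on real,
noisy, incomplete structures — protonation-state errors, unusual ligand
chemistry, metal sites with partial occupancy, or disorder are not
represented. The accession-backed integration tests (2E2H, 6G99) cover a
slice of that and require the user to supply the deposited files, since the
engine is offline by design.

## Numerical choices

- Plane fitting by SVD; planarity RMSD is the smallest singular value
  scaled by √n. The independent test oracle uses Newell's method instead,
  so plane agreement is a genuine cross-check.
- Coordinates are finite by construction (parse-time check).
- Degenerate inputs: ligands with no heavy atoms yield empty sites; empty
  sites are reported as "no contacts", never as errors; a structure with no
  ligand at all produces a valid empty report and exit code 0.
- Determinism: all outputs are totally ordered (sites by ligand chain/
  number, interactions by fixed catalogue order, then receptor residue
  key, then distance, then serials); two runs on the same input are
  byte-identical.
- Report numbers are fixed at two decimals; the in-memory records keep
  full precision and are what the acceptance machinery compares.

## Known limitations

- Generic ligand perception infers bond orders from geometry (C–O and C–N
  bond-length cutoffs); exotic tautomers, charged heteroaromatics and
  organometallics may be mis-perceived. Templates cover only standard
  residues and nucleotides.
- Aliphatic secondary/tertiary amines are uniformly assumed protonated;
  no pKa model.
- Hydroxyl hydrogen orientation is nearest-polar-atom heuristic, not an
  energy optimisation; donor angles through rotatable hydroxyls are
  therefore approximate on real structures.
- A nucleic chain is globally receptor or globally ligand per run; one
  chain cannot play both roles in a single analysis.
- No symmetry-mate generation, no covalent-bond reporting, no energy or
  strength scoring; mmCIF input is out of scope.
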