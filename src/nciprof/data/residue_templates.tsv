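# nciprof residue feature templates, version 1
# residue	feature	atoms	param
# feature one of: donor (param = number of hydrogens), acceptor,
# pos_charge, pos_charge_conditional, neg_charge, ring (ordered atoms).
# Backbone features (amide N donor, carbonyl O / OXT acceptor) and the
# all-carbon-neighbour hydrophobic rule are applied in code, not listed here.
# Protonation states assume pH 7: Asp/Glu deprotonated, Arg/Lys protonated,
# His cationic only when both ring nitrogens carry hydrogens.
ARG	donor	NE	1
ARG	donor	NH1	2
ARG	donor	NH2	2
ARG	pos_charge	CZ,NH1,NH2,NE	guanidinium
ASN	donor	ND2	2
ASN	acceptor	OD1
ASP	acceptor	OD1
ASP	acceptor	OD2
ASP	neg_charge	OD1,OD2	carboxylate
CYS	donor	SG	1
GLN	donor	NE2	2
GLN	acceptor	OE1
GLU	acceptor	OE1
GLU	acceptor	OE2
GLU	neg_charge	OE1,OE2	carboxylate
HIS	donor	ND1	1
HIS	donor	NE2	1
HIS	acceptor	ND1
HIS	acceptor	NE2
HIS	ring	CG,ND1,CE1,NE2,CD2
HIS	pos_charge_conditional	CG,ND1,CE1,NE2,CD2	imidazolium
LYS	donor	NZ	3
LYS	pos_charge	NZ	ammonium
PHE	ring	CG,CD1,CE1,CZ,CE2,CD2
SER	donor	OG	1
SER	acceptor	OG
THR	donor	OG1	1
THR	acceptor	OG1
TRP	donor	NE1	1
TRP	ring	CG,CD1,NE1,CE2,CD2
TRP	ring	CE2,CD2,CE3,CZ3,CH2,CZ2
TYR	donor	OH	1
TYR	acceptor	OH
TYR	ring	CG,CD1,CE1,CZ,CE2,CD2
# --- nucleotides: bases share templates between RNA and DNA forms.
# Phosphate/sugar features (OP1/OP2 negative centre and acceptors, RNA O2'
# donor+acceptor, O4' acceptor) are applied in code for every nucleotide.
A	ring	N1,C2,N3,C4,C5,C6
A	ring	C4,C5,N7,C8,N9
A	donor	N6	2
A	acceptor	N1
A	acceptor	N3
A	acceptor	N7
DA	ring	N1,C2,N3,C4,C5,C6
DA	ring	C4,C5,N7,C8,N9
DA	donor	N6	2
DA	acceptor	N1
DA	acceptor	N3
DA	acceptor	N7
G	ring	N1,C2,N3,C4,C5,C6
G	ring	C4,C5,N7,C8,N9
G	donor	N1	1
G	donor	N2	2
G	acceptor	O6
G	acceptor	N3
G	acceptor	N7
DG	ring	N1,C2,N3,C4,C5,C6
DG	ring	C4,C5,N7,C8,N9
DG	donor	N1	1
DG	donor	N2	2
DG	acceptor	O6
DG	acceptor	N3
DG	acceptor	N7
C	ring	N1,C2,N3,C4,C5,C6
C	donor	N4	2
C	acceptor	O2
C	acceptor	N3
DC	ring	N1,C2,N3,C4,C5,C6
DC	donor	N4	2
DC	acceptor	O2
DC	acceptor	N3
U	ring	N1,C2,N3,C4,C5,C6
U	donor	N3	1
U	acceptor	O2
U	acceptor	O4
DT	ring	N1,C2,N3,C4,C5,C6
DT	donor	N3	1
DT	acceptor	O2
DT	acceptor	O4
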