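# Synthetic per-atom hydropathy scale (kcal/mol per atom).
#
# This is a synthetic stand-in constructed by classifying every protein atom
# as apolar (hydrophobic) or polar (hydrophilic) from its chemical group, in
# the spirit of atomic hydropathy scales that threshold the magnitude of the
# atomic partial charge.  Apolar atoms (aliphatic/aromatic C, thioether S and
# their hydrogens) score +0.25; polar atoms (N, O, carbonyl/carboxamide/
# carboxylate/guanidinium C, hydroxyl/thiol/amide hydrogens) score -0.25.
#
# SIGN CONVENTION: hydrophobic = positive.  Downstream topology labelling
# keys off this via the `hydrophobic_sign` configuration flag (+1 here).
#
# Lookup precedence: exact (residue, atom) > residue wildcard ("HB*") >
# ("*", atom) > ("*", wildcard) > element default ("*", "@<element>").
residue_name	atom_name	hi
# --- element-level defaults (fallbacks, used with a warning) ---
*	@H	0.25
*	@C	0.25
*	@N	-0.25
*	@O	-0.25
*	@S	0.25
*	@P	-0.25
# --- backbone, all residues ---
*	CA	0.25
*	HA*	0.25
*	OXT	-0.25
*	H2	-0.25
*	H3	-0.25
# backbone amide N/H and carbonyl C/O are polar; the bare names N, C, O and H
# fall through to ("*", atom) exact rows below
# --- side chains ---
ALA	CB	0.25
ALA	HB*	0.25
ARG	CB	0.25
ARG	CG	0.25
ARG	CD	0.25
ARG	NE	-0.25
ARG	CZ	-0.25
ARG	NH1	-0.25
ARG	NH2	-0.25
ARG	HB*	0.25
ARG	HG*	0.25
ARG	HD*	0.25
ARG	HE	-0.25
ARG	HH*	-0.25
ASN	CB	0.25
ASN	CG	-0.25
ASN	OD1	-0.25
ASN	ND2	-0.25
ASN	HB*	0.25
ASN	HD2*	-0.25
ASP	CB	0.25
ASP	CG	-0.25
ASP	OD1	-0.25
ASP	OD2	-0.25
ASP	HB*	0.25
ASP	HD2	-0.25
CYS	CB	0.25
CYS	SG	0.25
CYS	HB*	0.25
CYS	HG	-0.25
GLN	CB	0.25
GLN	CG	0.25
GLN	CD	-0.25
GLN	OE1	-0.25
GLN	NE2	-0.25
GLN	HB*	0.25
GLN	HG*	0.25
GLN	HE2*	-0.25
GLU	CB	0.25
GLU	CG	0.25
GLU	CD	-0.25
GLU	OE1	-0.25
GLU	OE2	-0.25
GLU	HB*	0.25
GLU	HG*	0.25
GLU	HE2	-0.25
HIS	CB	0.25
HIS	CG	0.25
HIS	ND1	-0.25
HIS	CD2	0.25
HIS	CE1	-0.25
HIS	NE2	-0.25
HIS	HB*	0.25
HIS	HD1	-0.25
HIS	HD2	0.25
HIS	HE1	0.25
HIS	HE2	-0.25
ILE	CB	0.25
ILE	CG1	0.25
ILE	CG2	0.25
ILE	CD1	0.25
ILE	HB	0.25
ILE	HG*	0.25
ILE	HD*	0.25
LEU	CB	0.25
LEU	CG	0.25
LEU	CD1	0.25
LEU	CD2	0.25
LEU	HB*	0.25
LEU	HG	0.25
LEU	HD*	0.25
LYS	CB	0.25
LYS	CG	0.25
LYS	CD	0.25
LYS	CE	0.25
LYS	NZ	-0.25
LYS	HB*	0.25
LYS	HG*	0.25
LYS	HD*	0.25
LYS	HE*	0.25
LYS	HZ*	-0.25
MET	CB	0.25
MET	CG	0.25
MET	SD	0.25
MET	CE	0.25
MET	HB*	0.25
MET	HG*	0.25
MET	HE*	0.25
PHE	CB	0.25
PHE	CG	0.25
PHE	CD1	0.25
PHE	CD2	0.25
PHE	CE1	0.25
PHE	CE2	0.25
PHE	CZ	0.25
PHE	HB*	0.25
PHE	HD*	0.25
PHE	HE*	0.25
PHE	HZ	0.25
PRO	CB	0.25
PRO	CG	0.25
PRO	CD	0.25
PRO	HB*	0.25
PRO	HG*	0.25
PRO	HD*	0.25
SER	CB	0.25
SER	OG	-0.25
SER	HB*	0.25
SER	HG	-0.25
THR	CB	0.25
THR	OG1	-0.25
THR	CG2	0.25
THR	HB	0.25
THR	HG1	-0.25
THR	HG2*	0.25
TRP	CB	0.25
TRP	CG	0.25
TRP	CD1	0.25
TRP	CD2	0.25
TRP	NE1	-0.25
TRP	CE2	0.25
TRP	CE3	0.25
TRP	CZ2	0.25
TRP	CZ3	0.25
TRP	CH2	0.25
TRP	HB*	0.25
TRP	HD1	0.25
TRP	HE1	-0.25
TRP	HE3	0.25
TRP	HZ*	0.25
TRP	HH2	0.25
TYR	CB	0.25
TYR	CG	0.25
TYR	CD1	0.25
TYR	CD2	0.25
TYR	CE1	0.25
TYR	CE2	0.25
TYR	CZ	-0.25
TYR	OH	-0.25
TYR	HB*	0.25
TYR	HD*	0.25
TYR	HE*	0.25
TYR	HH	-0.25
VAL	CB	0.25
VAL	CG1	0.25
VAL	CG2	0.25
VAL	HB	0.25
VAL	HG*	0.25
# --- backbone bare names (exact, any residue) ---
*	N	-0.25
*	C	-0.25
*	O	-0.25
*	H	-0.25
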