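# pharmacophore class assignment, version 1
# columns: residue<TAB>atom<TAB>comma-separated classes
# classes: hydrophobic positive negative acceptor donor aromatic sulphur neutral
ALA	N	donor
ALA	CA	neutral
ALA	C	neutral
ALA	O	acceptor
ALA	OXT	negative,acceptor
ALA	CB	hydrophobic
ARG	N	donor
ARG	CA	neutral
ARG	C	neutral
ARG	O	acceptor
ARG	OXT	negative,acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	neutral
ARG	NE	positive,donor
ARG	CZ	positive
ARG	NH1	positive,donor
ARG	NH2	positive,donor
ASN	N	donor
ASN	CA	neutral
ASN	C	neutral
ASN	O	acceptor
ASN	OXT	negative,acceptor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	OD1	acceptor
ASN	ND2	donor
ASP	N	donor
ASP	CA	neutral
ASP	C	neutral
ASP	O	acceptor
ASP	OXT	negative,acceptor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	negative,acceptor
ASP	OD2	negative,acceptor
CYS	N	donor
CYS	CA	neutral
CYS	C	neutral
CYS	O	acceptor
CYS	OXT	negative,acceptor
CYS	CB	hydrophobic
CYS	SG	sulphur
GLN	N	donor
GLN	CA	neutral
GLN	C	neutral
GLN	O	acceptor
GLN	OXT	negative,acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	neutral
GLN	OE1	acceptor
GLN	NE2	donor
GLU	N	donor
GLU	CA	neutral
GLU	C	neutral
GLU	O	acceptor
GLU	OXT	negative,acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	neutral
GLU	OE1	negative,acceptor
GLU	OE2	negative,acceptor
GLY	N	donor
GLY	CA	neutral
GLY	C	neutral
GLY	O	acceptor
GLY	OXT	negative,acceptor
HIS	N	donor
HIS	CA	neutral
HIS	C	neutral
HIS	O	acceptor
HIS	OXT	negative,acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	aromatic,positive,donor,acceptor
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	aromatic,positive,donor,acceptor
ILE	N	donor
ILE	CA	neutral
ILE	C	neutral
ILE	O	acceptor
ILE	OXT	negative,acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
LEU	N	donor
LEU	CA	neutral
LEU	C	neutral
LEU	O	acceptor
LEU	OXT	negative,acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LYS	N	donor
LYS	CA	neutral
LYS	C	neutral
LYS	O	acceptor
LYS	OXT	negative,acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	neutral
LYS	NZ	positive,donor
MET	N	donor
MET	CA	neutral
MET	C	neutral
MET	O	acceptor
MET	OXT	negative,acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	sulphur
MET	CE	hydrophobic
PHE	N	donor
PHE	CA	neutral
PHE	C	neutral
PHE	O	acceptor
PHE	OXT	negative,acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic,hydrophobic
PHE	CD1	aromatic,hydrophobic
PHE	CD2	aromatic,hydrophobic
PHE	CE1	aromatic,hydrophobic
PHE	CE2	aromatic,hydrophobic
PHE	CZ	aromatic,hydrophobic
PRO	N	neutral
PRO	CA	neutral
PRO	C	neutral
PRO	O	acceptor
PRO	OXT	negative,acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	neutral
SER	N	donor
SER	CA	neutral
SER	C	neutral
SER	O	acceptor
SER	OXT	negative,acceptor
SER	CB	neutral
SER	OG	donor,acceptor
THR	N	donor
THR	CA	neutral
THR	C	neutral
THR	O	acceptor
THR	OXT	negative,acceptor
THR	CB	neutral
THR	OG1	donor,acceptor
THR	CG2	hydrophobic
TRP	N	donor
TRP	CA	neutral
TRP	C	neutral
TRP	O	acceptor
TRP	OXT	negative,acceptor
TRP	CB	hydrophobic
TRP	NE1	aromatic,donor
TRP	CG	aromatic,hydrophobic
TRP	CD1	aromatic,hydrophobic
TRP	CD2	aromatic,hydrophobic
TRP	CE2	aromatic,hydrophobic
TRP	CE3	aromatic,hydrophobic
TRP	CZ2	aromatic,hydrophobic
TRP	CZ3	aromatic,hydrophobic
TRP	CH2	aromatic,hydrophobic
TYR	N	donor
TYR	CA	neutral
TYR	C	neutral
TYR	O	acceptor
TYR	OXT	negative,acceptor
TYR	CB	hydrophobic
TYR	OH	donor,acceptor
TYR	CG	aromatic,hydrophobic
TYR	CD1	aromatic,hydrophobic
TYR	CD2	aromatic,hydrophobic
TYR	CE1	aromatic,hydrophobic
TYR	CE2	aromatic,hydrophobic
TYR	CZ	aromatic,hydrophobic
VAL	N	donor
VAL	CA	neutral
VAL	C	neutral
VAL	O	acceptor
VAL	OXT	negative,acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
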