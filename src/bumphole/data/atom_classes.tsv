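# Mapping from (residue 1-letter code, PDB atom name) to united-atom LJ class.
# The residue code '*' matches any residue (backbone atoms); an exact
# residue row overrides it (e.g. glycine CA is a CH2).
# res	atom	class
*	N	N
*	CA	CH1
*	C	CSP2
*	O	O
*	OXT	O
G	CA	CH2
A	CB	CH3
S	CB	CH2
S	OG	OH
C	CB	CH2
C	SG	S
T	CB	CH1
T	OG1	OH
T	CG2	CH3
V	CB	CH1
V	CG1	CH3
V	CG2	CH3
P	CB	CH2
P	CG	CH2
P	CD	CH2
I	CB	CH1
I	CG1	CH2
I	CG2	CH3
I	CD1	CH3
L	CB	CH2
L	CG	CH1
L	CD1	CH3
L	CD2	CH3
M	CB	CH2
M	CG	CH2
M	SD	S
M	CE	CH3
D	CB	CH2
D	CG	CSP2
D	OD1	O
D	OD2	O
N	CB	CH2
N	CG	CSP2
N	OD1	O
N	ND2	N
E	CB	CH2
E	CG	CH2
E	CD	CSP2
E	OE1	O
E	OE2	O
Q	CB	CH2
Q	CG	CH2
Q	CD	CSP2
Q	OE1	O
Q	NE2	N
K	CB	CH2
K	CG	CH2
K	CD	CH2
K	CE	CH2
K	NZ	N
R	CB	CH2
R	CG	CH2
R	CD	CH2
R	NE	N
R	CZ	CSP2
R	NH1	N
R	NH2	N
H	CB	CH2
H	CG	CSP2
H	ND1	N
H	CD2	CAR
H	CE1	CAR
H	NE2	N
F	CB	CH2
F	CG	CSP2
F	CD1	CAR
F	CD2	CAR
F	CE1	CAR
F	CE2	CAR
F	CZ	CAR
Y	CB	CH2
Y	CG	CSP2
Y	CD1	CAR
Y	CD2	CAR
Y	CE1	CAR
Y	CE2	CAR
Y	CZ	CSP2
Y	OH	OH
W	CB	CH2
W	CG	CSP2
W	CD1	CAR
W	CD2	CSP2
W	NE1	N
W	CE2	CSP2
W	CE3	CAR
W	CZ2	CAR
W	CZ3	CAR
W	CH2	CAR
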