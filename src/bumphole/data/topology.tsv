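# Ideal internal-coordinate table for side-chain heavy atoms (version 1).
# Each atom is placed from three previously known atoms by NeRF construction:
#   torsion(atom, a1, a2, a3) = torsion ; angle(atom, a1, a2) = angle ; |atom - a1| = bond
# torsion is either a chi label with optional offset (chi1, chi2+180, ...) or a fixed value
# in degrees. Bond lengths in Angstrom, angles/torsions in degrees.
# CB is placed as an improper off the backbone (torsion CB-CA-N-C = -122.5, L-chirality).
# res	atom	a1	a2	a3	bond	angle	torsion
A	CB	CA	N	C	1.530	110.4	-122.5
S	CB	CA	N	C	1.530	110.4	-122.5
S	OG	CB	CA	N	1.417	110.8	chi1
C	CB	CA	N	C	1.530	110.4	-122.5
C	SG	CB	CA	N	1.808	113.8	chi1
T	CB	CA	N	C	1.530	110.4	-122.5
T	OG1	CB	CA	N	1.433	109.6	chi1
T	CG2	CB	CA	N	1.521	110.5	chi1-120
V	CB	CA	N	C	1.530	110.4	-122.5
V	CG1	CB	CA	N	1.527	110.5	chi1
V	CG2	CB	CA	N	1.527	110.5	chi1+122
P	CB	CA	N	C	1.530	103.0	-120.0
P	CG	CB	CA	N	1.492	104.8	chi1
P	CD	CG	CB	CA	1.503	106.1	chi2
I	CB	CA	N	C	1.530	110.4	-122.5
I	CG1	CB	CA	N	1.530	110.4	chi1
I	CG2	CB	CA	N	1.521	110.5	chi1-122
I	CD1	CG1	CB	CA	1.513	113.8	chi2
L	CB	CA	N	C	1.530	110.4	-122.5
L	CG	CB	CA	N	1.530	116.3	chi1
L	CD1	CG	CB	CA	1.521	110.7	chi2
L	CD2	CG	CB	CA	1.521	110.7	chi2+122
M	CB	CA	N	C	1.530	110.4	-122.5
M	CG	CB	CA	N	1.520	114.1	chi1
M	SD	CG	CB	CA	1.803	112.7	chi2
M	CE	SD	CG	CB	1.791	100.9	chi3
D	CB	CA	N	C	1.530	110.4	-122.5
D	CG	CB	CA	N	1.516	112.6	chi1
D	OD1	CG	CB	CA	1.249	118.4	chi2
D	OD2	CG	CB	CA	1.249	118.4	chi2+180
N	CB	CA	N	C	1.530	110.4	-122.5
N	CG	CB	CA	N	1.516	112.6	chi1
N	OD1	CG	CB	CA	1.231	120.8	chi2
N	ND2	CG	CB	CA	1.328	116.4	chi2+180
E	CB	CA	N	C	1.530	110.4	-122.5
E	CG	CB	CA	N	1.520	114.1	chi1
E	CD	CG	CB	CA	1.516	112.6	chi2
E	OE1	CD	CG	CB	1.249	118.4	chi3
E	OE2	CD	CG	CB	1.249	118.4	chi3+180
Q	CB	CA	N	C	1.530	110.4	-122.5
Q	CG	CB	CA	N	1.520	114.1	chi1
Q	CD	CG	CB	CA	1.516	112.6	chi2
Q	OE1	CD	CG	CB	1.231	120.8	chi3
Q	NE2	CD	CG	CB	1.328	116.4	chi3+180
K	CB	CA	N	C	1.530	110.4	-122.5
K	CG	CB	CA	N	1.520	114.1	chi1
K	CD	CG	CB	CA	1.520	111.3	chi2
K	CE	CD	CG	CB	1.520	111.3	chi3
K	NZ	CE	CD	CG	1.489	111.9	chi4
R	CB	CA	N	C	1.530	110.4	-122.5
R	CG	CB	CA	N	1.520	114.1	chi1
R	CD	CG	CB	CA	1.520	111.3	chi2
R	NE	CD	CG	CB	1.460	112.0	chi3
R	CZ	NE	CD	CG	1.329	124.2	chi4
R	NH1	CZ	NE	CD	1.326	120.0	0
R	NH2	CZ	NE	CD	1.326	120.0	180
H	CB	CA	N	C	1.530	110.4	-122.5
H	CG	CB	CA	N	1.497	113.8	chi1
H	ND1	CG	CB	CA	1.371	122.7	chi2
H	CD2	CG	CB	CA	1.356	131.4	chi2+180
H	CE1	ND1	CG	CB	1.319	109.3	180
H	NE2	CE1	ND1	CG	1.374	111.7	0
F	CB	CA	N	C	1.530	110.4	-122.5
F	CG	CB	CA	N	1.504	113.9	chi1
F	CD1	CG	CB	CA	1.384	120.8	chi2
F	CD2	CG	CB	CA	1.384	120.8	chi2+180
F	CE1	CD1	CG	CB	1.382	120.8	180
F	CE2	CD2	CG	CB	1.382	120.8	180
F	CZ	CE1	CD1	CG	1.382	120.0	0
Y	CB	CA	N	C	1.530	110.4	-122.5
Y	CG	CB	CA	N	1.504	113.9	chi1
Y	CD1	CG	CB	CA	1.384	120.8	chi2
Y	CD2	CG	CB	CA	1.384	120.8	chi2+180
Y	CE1	CD1	CG	CB	1.382	120.8	180
Y	CE2	CD2	CG	CB	1.382	120.8	180
Y	CZ	CE1	CD1	CG	1.382	120.0	0
Y	OH	CZ	CE1	CD1	1.376	119.9	180
W	CB	CA	N	C	1.530	110.4	-122.5
W	CG	CB	CA	N	1.498	113.6	chi1
W	CD1	CG	CB	CA	1.365	126.9	chi2
W	CD2	CG	CB	CA	1.433	126.6	chi2+180
W	NE1	CD1	CG	CB	1.374	110.2	180
W	CE2	CD2	CG	CB	1.409	107.2	180
W	CE3	CD2	CG	CB	1.398	133.9	0
W	CZ2	CE2	CD2	CG	1.394	122.4	180
W	CZ3	CE3	CD2	CG	1.382	118.6	180
W	CH2	CZ2	CE2	CD2	1.368	117.5	0
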