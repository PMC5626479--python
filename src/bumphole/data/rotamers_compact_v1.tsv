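# Compact backbone-independent rotamer library "compact-v1".
# Canonical gauche-/gauche+/trans chi combinations with approximate
# population weights from surveyed high-resolution structures; weights are
# renormalized per residue type at load time. Angles in degrees.
# res	chi1	chi2	chi3	chi4	weight
A	.	.	.	.	1.00
G	.	.	.	.	1.00
S	62	.	.	.	0.48
S	-65	.	.	.	0.29
S	180	.	.	.	0.23
C	-65	.	.	.	0.55
C	180	.	.	.	0.26
C	62	.	.	.	0.19
T	62	.	.	.	0.49
T	-60	.	.	.	0.43
T	180	.	.	.	0.08
V	175	.	.	.	0.73
V	-60	.	.	.	0.20
V	63	.	.	.	0.07
P	27	-35	.	.	0.50
P	-27	35	.	.	0.50
L	-65	175	.	.	0.60
L	177	65	.	.	0.30
L	-85	65	.	.	0.05
L	-65	65	.	.	0.05
I	-65	170	.	.	0.60
I	-57	-60	.	.	0.15
I	62	170	.	.	0.13
I	-177	163	.	.	0.12
M	-65	-65	-70	.	0.25
M	-65	175	75	.	0.20
M	-65	175	180	.	0.20
M	180	175	75	.	0.20
M	180	180	180	.	0.15
F	-65	-85	.	.	0.44
F	177	80	.	.	0.34
F	62	90	.	.	0.13
F	-65	-30	.	.	0.09
Y	-65	-85	.	.	0.44
Y	177	80	.	.	0.34
Y	62	90	.	.	0.13
Y	-65	-30	.	.	0.09
W	-65	95	.	.	0.30
W	-177	90	.	.	0.20
W	-177	-105	.	.	0.15
W	-65	-5	.	.	0.15
W	62	-90	.	.	0.20
H	-65	-70	.	.	0.30
H	177	-165	.	.	0.25
H	-65	165	.	.	0.25
H	62	-75	.	.	0.20
D	-70	-15	.	.	0.51
D	-177	0	.	.	0.29
D	62	-10	.	.	0.20
N	-65	-40	.	.	0.40
N	-177	30	.	.	0.30
N	62	-20	.	.	0.30
E	-65	180	-10	.	0.30
E	180	180	0	.	0.25
E	-65	-65	-40	.	0.20
E	180	65	10	.	0.15
E	62	180	0	.	0.10
Q	-65	180	-25	.	0.30
Q	180	180	0	.	0.25
Q	-65	-65	-40	.	0.20
Q	180	65	100	.	0.15
Q	62	180	20	.	0.10
K	-65	180	180	180	0.30
K	180	180	180	180	0.25
K	-65	180	180	-65	0.20
K	-65	-65	180	180	0.15
K	180	180	180	65	0.10
R	-65	180	180	180	0.30
R	180	180	180	180	0.25
R	-65	-65	180	180	0.20
R	-65	180	180	-85	0.15
R	180	65	65	85	0.10
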