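# United heavy-atom 12-6 Lennard-Jones parameters (version 1).
# Magnitudes follow common united-atom force-field practice (OPLS-UA-like):
# implicit hydrogens are folded into the carbon radii. sigma in Angstrom,
# epsilon in kcal/mol.
# class	sigma	epsilon
CH3	3.775	0.207
CH2	3.905	0.118
CH1	3.850	0.080
CAR	3.750	0.110
CSP2	3.750	0.105
N	3.250	0.170
O	2.960	0.210
OH	3.070	0.170
S	3.550	0.250
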