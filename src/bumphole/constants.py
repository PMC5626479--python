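"""Amino-acid naming tables shared across the package."""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA3_TO_1)

# Backbone heavy atoms of the peptide unit; everything else is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# Number of chi dihedrals per residue type (1-letter codes).
N_CHI = {
    "A": 0, "G": 0, "S": 1, "C": 1, "T": 1, "V": 1,
    "P": 2, "I": 2, "L": 2, "D": 2, "N": 2, "H": 2, "F": 2, "Y": 2, "W": 2,
    "M": 3, "E": 3, "Q": 3, "K": 4, "R": 4,
}

# Side-chain heavy atoms per residue type, in build order.
SIDECHAIN_ATOMS = {
    "A": ["CB"],
    "G": [],
    "S": ["CB", "OG"],
    "C": ["CB", "SG"],
    "T": ["CB", "OG1", "CG2"],
    "V": ["CB", "CG1", "CG2"],
    "P": ["CB", "CG", "CD"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "M": ["CB", "CG", "SD", "CE"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}
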