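"""Shared constants: amino-acid alphabet, mask bit order, ideal mainchain geometry.

The 20-letter alphabet is fixed in alphabetical one-letter order; bit ``i`` of a
residue-type mask corresponds to ``AA_ALPHABET[i]``.  This ordering is part of the
database file format and must never change.
"""

from __future__ import annotations

#: One-letter amino-acid codes in mask bit order (bit 0 = 'A' ... bit 19 = 'Y').
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Mask with all 20 type bits set (no restriction).
FULL_MASK = (1 << 20) - 1

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Modified residues mapped to their parent standard type; anything else is excluded
#: from database builds so the 20-bit mask semantics stay clean.
MODIFIED_PARENT = {
    "MSE": "MET",  # selenomethionine
    "CSO": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "HYP": "PRO",
}

#: Sentinel for undefined distance-matrix entries; negative so it can never be
#: confused with a real distance.
FLAG = -1.0

#: Default running-distance-matrix width: rows hold distances to the following 20
#: residues, supporting search fragments of up to 21 residues.
DEFAULT_WIDTH = 20

#: Default Calpha B-factor ceiling for database admission (A^2).
DEFAULT_B_MAX = 40.0

#: Residues i, i+1 are continuous iff the C(i)-N(i+1) distance is at most this (A);
#: covers distorted peptide bonds (~1.33 A ideal) while rejecting chain jumps.
CONTINUITY_CN_MAX = 1.8

# --- ideal mainchain geometry (Engh & Huber style) -------------------------------
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_CB = 1.53
BOND_C_O = 1.23
ANGLE_N_CA_C = 111.2    # degrees
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_CB = 110.5
ANGLE_CA_C_O = 121.0
OMEGA_TRANS = 180.0
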