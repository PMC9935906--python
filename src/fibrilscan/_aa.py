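"""Amino-acid tables shared across the package.

One-letter codes are the internal currency; three-letter codes appear only
at the PDB/mmCIF boundary.  The side-chain templates describe the simplified
pseudo-atom representation used by the synthetic fibril builder: heavy atoms
beyond CB are laid out as a short chain along the side-chain direction, with
element assignments chosen so that size, nonpolarity and charge orderings
between residue types are preserved.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL = frozenset(ONE_TO_THREE)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain pseudo-atoms beyond CB: (atom name, element, level, lateral).
# ``level`` counts 1.3 Å shells outward along the (slightly kinked) side-chain
# axis; ``lateral`` fans branch atoms to either side of it.  The layout keeps
# residue-size and polarity orderings without rotamer-level realism.
SIDECHAIN_TEMPLATE: dict[str, list[tuple[str, str, int, int]]] = {
    "G": [],
    "A": [],
    "S": [("OG", "O", 1, 0)],
    "C": [("SG", "S", 1, 0)],
    "T": [("OG1", "O", 1, 1), ("CG2", "C", 1, -1)],
    "V": [("CG1", "C", 1, 1), ("CG2", "C", 1, -1)],
    "P": [("CG", "C", 1, 1), ("CD", "C", 1, -1)],
    "L": [("CG", "C", 1, 0), ("CD1", "C", 2, 1), ("CD2", "C", 2, -1)],
    "I": [("CG1", "C", 1, 1), ("CG2", "C", 1, -1), ("CD1", "C", 2, 1)],
    "M": [("CG", "C", 1, 0), ("SD", "S", 2, 0), ("CE", "C", 3, 0)],
    "N": [("CG", "C", 1, 0), ("OD1", "O", 2, 1), ("ND2", "N", 2, -1)],
    "D": [("CG", "C", 1, 0), ("OD1", "O", 2, 1), ("OD2", "O", 2, -1)],
    "Q": [("CG", "C", 1, 0), ("CD", "C", 2, 0), ("OE1", "O", 3, 1), ("NE2", "N", 3, -1)],
    "E": [("CG", "C", 1, 0), ("CD", "C", 2, 0), ("OE1", "O", 3, 1), ("OE2", "O", 3, -1)],
    "H": [("CG", "C", 1, 0), ("ND1", "N", 2, 1), ("CE1", "C", 2, -1)],
    "F": [("CG", "C", 1, 0), ("CD1", "C", 2, 1), ("CD2", "C", 2, -1), ("CZ", "C", 3, 0)],
    "Y": [("CG", "C", 1, 0), ("CD1", "C", 2, 1), ("CD2", "C", 2, -1), ("CZ", "C", 3, 0),
          ("OH", "O", 4, 0)],
    "W": [("CG", "C", 1, 0), ("CD1", "C", 2, 1), ("CD2", "C", 2, -1), ("CE2", "C", 3, 1),
          ("CZ2", "C", 3, -1)],
    "K": [("CG", "C", 1, 0), ("CD", "C", 2, 0), ("CE", "C", 3, 0), ("NZ", "N", 4, 0)],
    "R": [("CG", "C", 1, 0), ("CD", "C", 2, 0), ("NE", "N", 3, 0), ("CZ", "C", 4, 0),
          ("NH1", "N", 4, 1)],
}

# Formal charge carried by a single side-chain group atom (screened-Coulomb
# centroids in the energy backend).  Termini are left neutral.
CHARGE_ATOMS: dict[str, tuple[str, float]] = {
    "K": ("NZ", +1.0),
    "R": ("CZ", +1.0),
    "D": ("OD1", -1.0),
    "E": ("OE1", -1.0),
}

NONPOLAR = frozenset("AVLIMFWPG")
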