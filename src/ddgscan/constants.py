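"""Shared physical constants and amino-acid reference tables.

Everything geometric in the package is heavy-atom only, so the radii table
carries no hydrogen entry for protein atoms (H is dropped at parse time).
"""

from __future__ import annotations

# Bondi van der Waals radii (Angstrom). Versioned: v1.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
    # common structural ions, retained as het groups
    "MG": 1.73,
    "ZN": 1.39,
    "MN": 1.73,
    "FE": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}

VDW_TABLE_VERSION = "bondi-v1"

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

# Idealized heavy-atom side-chain topology (standard PDB atom names).
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

# Aromatic ring systems per residue (Trp has two).
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
}

# Maximum solvent accessibility of residue X in an extended Gly-X-Gly
# tripeptide (theoretical values, Tien et al. 2013), Angstrom^2. Used for
# relative accessibility.
MAX_SASA_GLY_X_GLY: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Gas constant in kcal mol^-1 K^-1 and lab temperature in K: together they
# reproduce the 10-fold affinity-loss threshold of 1.36 kcal/mol.
GAS_CONSTANT_KCAL = 1.9872e-3
STANDARD_TEMPERATURE_K = 298.15
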