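"""Residue-level constants: amino-acid codes, functional atoms, reference areas.

The functional atom of a residue type is the side-chain atom (or pair of
atoms) between which inter-residue distances are measured — the charged or
chemically distinctive tip of the side chain (Cys SG, Lys NZ, ...).  Glycine,
having no side chain, uses its CA.
"""

from __future__ import annotations

# The 20 standard residues, alphabetical by 3-letter code.  This ordering is
# the bin order of the two amino-acid tensor dimensions.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Title-case display labels ("Ala" ... "Val").
AA_LABELS: tuple[str, ...] = tuple(aa.capitalize() for aa in AMINO_ACIDS)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Functional atoms per residue type (PDB atom nomenclature).  Residues with
# two listed atoms have a symmetric or bidentate functional group; pair
# distances take the minimum over atom combinations.
FUNCTIONAL_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("NH1", "NH2"),
    "ASN": ("ND2", "OD1"),
    "ASP": ("OD1", "OD2"),
    "CYS": ("SG",),
    "GLN": ("NE2", "OE1"),
    "GLU": ("OE1", "OE2"),
    "GLY": ("CA",),
    "HIS": ("ND1",),
    "ILE": ("CG1", "CG2"),
    "LEU": ("CG",),
    "LYS": ("NZ",),
    "MET": ("SD",),
    "PHE": ("CZ",),
    "PRO": ("CG",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("CE2",),
    "TYR": ("OH",),
    "VAL": ("CG1", "CG2"),
}

# Maximal accessible surface areas (Å²) of residue X in an extended
# Gly-X-Gly tripeptide (Chothia 1976 values as tabulated by Creighton,
# "Proteins: Structures and Molecular Properties").  Used to convert a
# residue's absolute SASA into a relative accessibility percentage; the
# table is a module-level constant so an alternative scale can be swapped in.
REFERENCE_AREAS: dict[str, float] = {
    "ALA": 115.0, "ARG": 225.0, "ASN": 160.0, "ASP": 150.0, "CYS": 135.0,
    "GLN": 180.0, "GLU": 190.0, "GLY": 75.0, "HIS": 195.0, "ILE": 175.0,
    "LEU": 170.0, "LYS": 200.0, "MET": 185.0, "PHE": 210.0, "PRO": 145.0,
    "SER": 115.0, "THR": 140.0, "TRP": 255.0, "TYR": 230.0, "VAL": 155.0,
}

# Four secondary-structure classes, in bin order.
SS_CLASSES: tuple[str, ...] = ("helix", "strand", "turn", "coil")
SS_INDEX: dict[str, int] = {ss: i for i, ss in enumerate(SS_CLASSES)}

# DSSP/HSSP 8-state code -> 4-class reduction.  Blank (no assignment) and
# 'C'/'-' placeholders map to coil.
SS_CODE_MAP: dict[str, str] = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "turn", "S": "turn",
    "C": "coil", " ": "coil", "-": "coil", "": "coil",
}

# Residue pair criterion: functional-atom distance strictly below this (Å).
# Equals the upper edge of the last spatial-distance bin.
DISTANCE_CUTOFF: float = 8.25
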