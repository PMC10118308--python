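"""Element radius tables, amino-acid dictionaries and RSA reference values."""

from __future__ import annotations

# Element-keyed van der Waals radii (Å); fallback for anything unlisted.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.80

# Elements treated as metals; metal-only ligands never enter scoring.
METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA",
    "V", "CR", "MO", "W", "PT", "PD", "AG", "AU",
}

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AMINO_ACIDS = sorted(AA_1TO3)

# The 7-member hydrophobic set used throughout (one-letter codes).
HYDROPHOBIC_SET = frozenset("CFILMVY")

# Theoretical maximum SASA (Å²) of residue X in an extended Gly-X-Gly
# tripeptide (Tien et al. 2013), used as the RSA denominator for full-atom
# structures.  Synthetic toy structures ship their own reference table.
MAX_SASA_GXG: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def vdw_radius(element: str) -> float:
    """Radius for an element symbol; unknown elements get the default."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
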