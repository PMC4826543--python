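"""Bundled per-residue physicochemical scales.

A small set of widely used amino-acid property scales, inlined so that
window-feature encoders work out of the box. For the full AAIndex
collection (hundreds of properties) use :func:`epidesign.encoders.read_aaindex1`
on a user-supplied AAIndex1 flat file.
"""

from __future__ import annotations

# Kyte & Doolittle hydropathy index
HYDROPATHY_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Hopp & Woods hydrophilicity
HYDROPHILICITY_HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

# Chou & Fasman alpha-helix propensity
HELIX_PROPENSITY_CHOU_FASMAN = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

# Chou & Fasman beta-sheet propensity
SHEET_PROPENSITY_CHOU_FASMAN = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

# Grantham polarity
POLARITY_GRANTHAM = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

# Average molecular weight of the free amino acid (Da)
MOLECULAR_WEIGHT = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}

# Isoelectric point of the free amino acid
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}

BUNDLED_PROPERTIES: dict[str, dict[str, float]] = {
    "hydropathy_kyte_doolittle": HYDROPATHY_KYTE_DOOLITTLE,
    "hydrophilicity_hopp_woods": HYDROPHILICITY_HOPP_WOODS,
    "helix_propensity_chou_fasman": HELIX_PROPENSITY_CHOU_FASMAN,
    "sheet_propensity_chou_fasman": SHEET_PROPENSITY_CHOU_FASMAN,
    "polarity_grantham": POLARITY_GRANTHAM,
    "molecular_weight": MOLECULAR_WEIGHT,
    "isoelectric_point": ISOELECTRIC_POINT,
}
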