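"""Per-element reference data used across the package.

Masses are standard atomic weights (amu). Covalent radii are the Cordero
(2008) single-bond values, used only for bond inference on plain XYZ input.
VDW_RADIUS holds Bondi (1964) van der Waals radii for the neighbor
criterion in coordination-number counting. VABC_CONTRIB holds the atomic
van der Waals volume contributions (Å³) of the Zhao–Abraham–Zissimos
additive volume scheme.
"""

from __future__ import annotations

MASS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180, "Na": 22.990, "Mg": 24.305,
    "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Ar": 39.948, "K": 39.098, "Ca": 40.078, "Br": 79.904, "I": 126.904,
    "Se": 78.971, "Te": 127.60, "As": 74.922, "Zn": 65.38, "Fe": 55.845,
}

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Br": 1.20, "I": 1.39, "Se": 1.20, "Te": 1.38, "As": 1.19, "Zn": 1.22,
    "Fe": 1.32,
}

VDW_RADIUS: dict[str, float] = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88, "K": 2.75, "Br": 1.85, "I": 1.98, "Se": 1.90,
    "Te": 2.06, "As": 1.85, "Zn": 1.39,
}

# Atomic contributions (Å³) for the additive vdW volume:
#   V = sum(contrib) - 5.92*N_bonds - 14.7*R_aromatic - 3.8*R_nonaromatic
VABC_CONTRIB: dict[str, float] = {
    "H": 7.24, "C": 20.58, "N": 15.60, "O": 14.71, "F": 13.31,
    "Cl": 22.45, "Br": 26.52, "I": 32.52, "P": 24.43, "S": 24.43,
    "As": 26.52, "B": 40.48, "Si": 38.79, "Se": 28.73, "Te": 36.62,
}

VABC_BOND_TERM = 5.92
VABC_AROMATIC_RING_TERM = 14.7
VABC_NONAROMATIC_RING_TERM = 3.8
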