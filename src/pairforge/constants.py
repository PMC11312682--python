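"""Physical constants and unit conversions.

Energies are kcal/mol, distances Å, charges elementary charges, masses amu,
time fs throughout the package.
"""

#: Boltzmann constant, kcal/(mol·K)
KB_KCAL = 1.987204259e-3

#: Coulomb prefactor, kcal·Å/(mol·e²), generic electrostatics
COULOMB_CONSTANT = 332.0637

#: Coulomb prefactor used by the MMFF94 force field
MMFF_COULOMB_CONSTANT = 332.0716

#: MMFF94 electrostatic buffering distance, Å
MMFF_COULOMB_BUFFER = 0.05

#: multiply a force in kcal/(mol·Å) by this and divide by mass in amu
#: to get acceleration in Å/fs²
ACCEL_CONVERSION = 4.184e-4

#: Boltzmann constant, amu·Å²/(fs²·K)
KB_MD = KB_KCAL * ACCEL_CONVERSION

#: per-molecule volume of liquid water at 298 K from density and molar mass, Å³
WATER_BOX_VOLUME = 30.00

#: van der Waals volume of a water molecule (additive scheme), Å³
WATER_VDW_VOLUME = 17.35
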