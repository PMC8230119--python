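"""Physical constants and unit conversions used throughout the package.

Internal length unit is the angstrom; energies are kJ/mol.
"""

#: Boltzmann constant in kJ/(mol K) (i.e. the molar gas constant).
KB_KJ_PER_MOL_K = 0.008314462618

#: Default temperature (K) for Boltzmann inversion when none is given.
DEFAULT_TEMPERATURE = 300.0

#: Bohr radius in angstrom (Gaussian cube files store Bohr).
BOHR_TO_ANGSTROM = 0.529177210903

#: Covalent radii (angstrom) for distance-based bond perception.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76,
}

#: Fallback covalent radius (angstrom) for elements not in the table.
DEFAULT_COVALENT_RADIUS = 0.77


def kT(temperature: float) -> float:
    """Thermal energy kT in kJ/mol at the given temperature in kelvin."""
    return KB_KJ_PER_MOL_K * temperature
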