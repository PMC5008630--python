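"""Physical constants and unit conventions.

Internal units throughout the package: length in angstrom (A), time in
picosecond (ps), energy in kcal/mol, charge in units of the elementary
charge e, temperature in kelvin.
"""

#: Boltzmann constant, kcal/(mol*K).
KB = 0.0019872

#: Coulomb prefactor, kcal*A/(mol*e^2): U = COULOMB * q1*q2 / (eps_r * r).
COULOMB = 332.06

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0

#: Default uniform relative dielectric of the toy Hamiltonian.
DEFAULT_DIELECTRIC = 10.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kT in kcal/mol at the given temperature (0.6160 kcal/mol at 310 K)."""
    return KB * temperature
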