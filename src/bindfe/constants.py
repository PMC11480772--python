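"""Physical constants and unit conventions.

All energies are in kcal/mol, lengths in Angstrom, angles in radians,
temperatures in Kelvin, charges in elementary charges unless stated
otherwise.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872041

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Volume per molecule at the 1 M standard state, A^3.
STANDARD_VOLUME = 1660.6

#: Coulomb prefactor q1*q2/r in vacuum, kcal mol^-1 A e^-2.
COULOMB_CONSTANT = 332.0637

#: Relative dielectric constant of water used by the coarse-grained toy model.
WATER_DIELECTRIC = 78.0

#: Debye length prefactor for a 1:1 electrolyte near 300 K:
#: lambda_D [A] = DEBYE_PREFACTOR / sqrt(I [M]).
DEBYE_PREFACTOR = 3.04


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature


def debye_length(ionic_strength_molar: float) -> float:
    """Debye screening length in Angstrom for a 1:1 electrolyte at ~300 K."""
    if ionic_strength_molar <= 0:
        raise ValueError("ionic strength must be positive")
    return DEBYE_PREFACTOR / ionic_strength_molar**0.5
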