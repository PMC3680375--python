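"""Physical constants and shared unit conversions.

All energies in the package are kcal/mol, lengths in Angstrom, charges in
units of the elementary charge e, concentrations in mol/L unless a function
says otherwise.
"""

# Gas constant, kcal/(mol K)
R_KCAL = 1.987204259e-3

# Default temperature (K); RT = 0.5925 kcal/mol at 298.15 K
DEFAULT_TEMPERATURE = 298.15

# 1 e*V in kcal/mol: converts electrostatic potential in volts to
# kcal/(mol e)
KCAL_PER_EVOLT = 23.060548

# Molar concentration of pure water, mol/L (used in standard-state
# conversions between mole-fraction and molarity scales)
WATER_MOLARITY = 55.3

# Relative dielectric constant of water near room temperature
WATER_DIELECTRIC = 78.5

# Average mass of a water molecule, g/mol (peptide-bond condensation)
WATER_MASS = 18.0153


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT in kcal/mol at the given temperature."""
    return R_KCAL * temperature
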