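"""Physical constants used throughout the package.

Single definition point: every module imports the Boltzmann constant from
here so that the value cannot drift between formulas.
"""

#: Boltzmann constant in eV per kelvin.
BOLTZMANN_EV: float = 8.617e-5

#: Additive offset between degrees Celsius and kelvin.
CELSIUS_OFFSET: float = 273.15


def celsius_to_kelvin(t_celsius):
    """Convert a temperature (scalar or array) from Celsius to kelvin."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert a temperature (scalar or array) from kelvin to Celsius."""
    return t_kelvin - CELSIUS_OFFSET
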