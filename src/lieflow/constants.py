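"""Physical constants and unit conventions.

All energies in this package are molar energies in kJ/mol; temperatures in
kelvin. ``k_B T`` therefore appears as ``R T`` with the molar gas constant.
"""

#: Molar gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT = 0.0083145

#: Default simulation / conversion temperature (K).
DEFAULT_TEMPERATURE = 300.0


def rt(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol for a temperature in kelvin."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT * temperature
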