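"""Physical constants and unit helpers."""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Default temperature (K) for kBT <-> kcal/mol conversion.
DEFAULT_TEMPERATURE_K = 298.15


def kbt_kcal(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
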