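"""Physical constants and unit helpers.

All internal frame times are picoseconds; reported residence times are
seconds; energies are kcal/mol; temperatures are kelvin.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Picoseconds per second.
PS_PER_S = 1.0e12

#: Default unbinding threshold on the ligand z position (angstrom).
DEFAULT_Z_THRESHOLD = 15.0

#: Default simulation temperature (kelvin).
DEFAULT_TEMPERATURE = 300.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/kT in mol/kcal at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL_PER_MOL_K * temperature)


def kt(temperature: float) -> float:
    """Thermal energy kT in kcal/mol at ``temperature`` kelvin."""
    return 1.0 / beta(temperature)
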