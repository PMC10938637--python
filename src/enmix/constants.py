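"""Physical constants and package-wide defaults (GROMACS units: nm, kJ/mol, K)."""

#: Boltzmann constant, kJ/mol/K.
KB = 0.00831446

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0

#: Default elastic-network force constant, kJ/mol/nm^2.
DEFAULT_FORCE_CONSTANT = 500.0

#: Default elastic-network distance cutoff, nm.
DEFAULT_CUTOFF = 0.9

#: Default number of blocks for block-averaged error estimates.
DEFAULT_N_BLOCKS = 5


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature
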