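"""Physical constants and unit conventions.

All energies in ktnkit are kcal/mol, temperatures in kelvin, rates in s^-1.
Vibrational frequencies enter only through stored log-products (ln of the
product of normal-mode frequencies in s^-1).
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: Boltzmann constant, J K^-1 (SI, for the Eyring prefactor)
KB_SI = 1.380649e-23

#: Planck constant, J s
H_SI = 6.62607015e-34

#: Default analysis temperature: 37 degC, the physiological temperature at
#: which the experimental exchange parameters were measured.
T_DEFAULT = 310.15


def beta(T: float) -> float:
    """1/(k_B T) in mol kcal^-1."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return 1.0 / (KB_KCAL * T)


def eyring_prefactor(T: float) -> float:
    """k_B T / h in s^-1 (the universal attempt frequency of the Eyring relation)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return KB_SI * T / H_SI
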