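"""Physical constants in the kcal/mol–Å–K unit system used throughout."""

#: Boltzmann constant in molar energy units, kcal mol^-1 K^-1.
KB_KCAL: float = 0.0019872041

#: k_B / h in s^-1 K^-1; multiplied by T it gives the Eyring prefactor k_B*T/h.
KB_OVER_H: float = 2.0836612e10

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 300.0
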