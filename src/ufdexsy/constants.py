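"""Physical constants used across the package (SI units)."""

#: Gyromagnetic ratio of 1H, rad s^-1 T^-1 (CODATA).
GAMMA_1H = 2.6752218744e8

#: Boltzmann constant, J K^-1.
K_BOLTZMANN = 1.380649e-23
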