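"""Physical constants and gyromagnetic ratios (SI, rad s^-1 T^-1)."""

HBAR = 1.054571817e-34  # J s
KB = 1.380649e-23       # J K^-1
MU0_OVER_4PI = 1.0e-7   # T m A^-1 -> N A^-2 / (4 pi)
NA = 6.02214076e23      # mol^-1

#: gyromagnetic ratios in rad s^-1 T^-1
GAMMA = {
    "1H": 267.52218744e6,
    "13C": 67.2828e6,
    "2H": 41.065e6,
    "e": -1.76085963023e11,  # free electron
}

ANGSTROM = 1.0e-10
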