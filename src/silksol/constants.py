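"""Physical constants used throughout the package.

Values are CODATA-2018 where exact; the gas constant is kept at the
4-significant-figure value conventionally used in solution thermodynamics
so that chemical potentials print on the familiar scale.
"""

AVOGADRO = 6.02214076e23  # mol^-1
GAS_CONSTANT = 8.314  # J mol^-1 K^-1
BOLTZMANN = 1.380649e-23  # J K^-1

WATER_MOLAR_MASS = 18.015  # g mol^-1
CP_WATER = 75.7  # J mol^-1 K^-1, molar heat capacity of liquid water
T_ZERO_C = 273.15  # K
TRIPLE_POINT_T = 273.16  # K
TRIPLE_POINT_P = 611.657  # Pa
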