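"""Physical constants and unit conversions used across the package.

All internal energies are eV, lengths Å, times ps (current analysis) or
seconds (kinetics); conversions to SI happen at module boundaries.
"""

ELEMENTARY_CHARGE_C = 1.602176634e-19  # C per e
KDA_TO_KG = 1.66053906660e-24  # kg per kDa
ANGSTROM_TO_M = 1e-10

# 1 e/ps expressed in nA; fixed convention, 7 significant figures.
E_PER_PS_IN_NA = 160.2177
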