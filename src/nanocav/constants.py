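"""Physical constants (CODATA 2018) and unit-conversion factors.

The continuum bubble models work in SI throughout; trajectory analysis works
in the MD dump units (Å, ps, amu, atm·Å³) and converts at the boundary.
"""

# CODATA 2018 exact values
BOLTZMANN = 1.380649e-23  # J/K
PLANCK = 6.62607015e-34  # J·s
AVOGADRO = 6.02214076e23  # 1/mol
AMU_TO_KG = 1.66053906660e-27  # kg
AMU_TO_G = 1.66053906660e-24  # g

# Pressure: per-atom virial stress is carried in atm·Å³ (LAMMPS dump convention)
ATM_TO_MPA = 0.101325
MPA_TO_ATM = 1.0 / ATM_TO_MPA

# Lengths / times / volumes
ANGSTROM_TO_M = 1e-10
PS_TO_S = 1e-12
A3_TO_CM3 = 1e-24
A3_TO_M3 = 1e-30

# Diffusion: Å²/ps -> m²/s
A2_PER_PS_TO_M2_PER_S = 1e-8
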