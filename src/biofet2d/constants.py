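"""Physical constants in SI units (CODATA 2018).

The 2019 SI redefinition fixes ``Q_E``, ``K_B`` and ``N_A`` exactly; the
remaining values are given to nine significant digits.
"""

#: Elementary charge, C (exact).
Q_E = 1.602176634e-19

#: Boltzmann constant, J/K (exact).
K_B = 1.380649e-23

#: Reduced Planck constant, J*s.
HBAR = 1.054571817e-34

#: Free-electron rest mass, kg.
M_E = 9.10938370e-31

#: Vacuum permittivity, F/m.
EPS_0 = 8.85418781e-12

#: Avogadro constant, 1/mol (exact).
N_A = 6.02214076e23
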