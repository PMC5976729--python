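"""Physical constants in the unit system used throughout the package.

Times are picoseconds, frequencies THz, lengths metres, fields V/m.
The product ``f_THz * t_ps`` is dimensionless, so Fourier pairs need no
unit conversion; only the speed of light has to be expressed in m/ps.
"""

#: speed of light, m/ps
C_M_PER_PS = 2.99792458e-4

#: speed of light, m/s
C_M_PER_S = 2.99792458e8

#: Boltzmann constant, J/K
K_B = 1.380649e-23

#: Avogadro constant, 1/mol
N_A = 6.02214076e23

#: reference temperature of the experiment, K
T_REF = 296.0
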