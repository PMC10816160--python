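"""Physical constants used throughout the package (SI-based)."""

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23

#: Unit in which the cohesion pressure ``a`` is tabulated: 1e-23 J L/mg.
#: With beta = 1/(kB T) this makes 2*a*beta*Ce dimensionless and O(1)
#: at typical metal concentrations (tens of mg/L).
A_UNIT = 1e-23
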