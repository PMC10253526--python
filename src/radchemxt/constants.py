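"""Physical constants and unit-conversion factors.

Internal unit system: length in nm, time in ns, concentration in mol/L.
Rate constants are stored per M per ns; the I/O layer accepts the
conventional M^-1 s^-1.
"""

AVOGADRO = 6.02214076e23  # 1/mol

#: 1 nm^3 expressed in litres.
NM3_TO_L = 1e-24

#: Conversion from M^-1 s^-1 to the internal M^-1 ns^-1.
K_SI_TO_INTERNAL = 1e-9

#: Default Henry's-law constant for O2 in water at 25 C, in M/atm.
DEFAULT_HENRY_O2 = 1.3e-3

#: Dose-fluence-LET prefactor: D[Gy] = 1.6e-9 * LET[keV/um] * Phi[1/cm^2] / rho.
DOSE_LET_PREFACTOR = 1.6e-9

#: 1 keV in eV (G-values are per 100 eV).
KEV_TO_EV = 1e3

CM_TO_NM = 1e7
CM3_TO_L = 1e-3
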