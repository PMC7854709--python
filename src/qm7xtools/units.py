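"""Physical constants and unit conversions.

Internal unit system: energies in eV, lengths in Angstrom, masses in amu.
Angular frequencies from mass-weighted Hessians therefore come out in
sqrt(eV / (amu * A^2)); :data:`OMEGA_TO_INV_CM` converts them to the
spectroscopist's wavenumber scale for reporting.
"""

import math

#: Boltzmann constant, eV/K (CODATA exact).
KB_EV = 8.617333262e-5

#: 1 kcal/mol in eV.
KCAL_PER_MOL_EV = 0.0433641

#: 1 eV in Joule (exact).
EV_J = 1.602176634e-19

#: 1 amu in kg.
AMU_KG = 1.66053906660e-27

#: Speed of light, cm/s.
C_CM_S = 2.99792458e10

#: 1 Bohr radius in Angstrom.
BOHR_A = 0.529177210903

# omega [sqrt(eV/(amu A^2))] -> omega [rad/s]
_OMEGA_TO_SI = math.sqrt(EV_J / (AMU_KG * 1e-20))

#: Multiply an internal angular frequency by this to obtain cm^-1.
OMEGA_TO_INV_CM = _OMEGA_TO_SI / (2.0 * math.pi * C_CM_S)

#: Internal angular frequency corresponding to 1 cm^-1.
INV_CM_TO_OMEGA = 1.0 / OMEGA_TO_INV_CM
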