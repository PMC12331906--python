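"""Physical constants in the unit system used throughout the package.

Time is carried in femtoseconds, wavenumbers in cm^-1, dipoles in Debye,
masses in unified atomic mass units. SI values follow CODATA 2018.
"""

#: Speed of light in cm/s.
C_CM_PER_S = 2.99792458e10

#: Speed of light in cm/fs (converts 1/(N*dt_fs) to a wavenumber).
C_CM_PER_FS = C_CM_PER_S * 1e-15

#: hc/k_B in cm*K: x = (hc/k_B) * nu[cm^-1] / T[K] is the photon energy in k_B*T units.
HC_OVER_KB_CM_K = 1.4387769

#: Planck constant times speed of light, J*cm (energy of a 1 cm^-1 quantum).
HC_J_CM = 6.62607015e-34 * C_CM_PER_S

#: Unified atomic mass unit in kg.
AMU_KG = 1.66053906660e-27
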