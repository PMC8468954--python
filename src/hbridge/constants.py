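"""Physical constants and unit conversions.

Working units throughout the package: Å (length), fs (time), amu (mass),
kcal/mol (energy), K (temperature).  The vibrational solver works internally
in Hartree atomic units.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: 1 kcal/mol expressed in amu Å^2 fs^-2 (4184 J/mol over 1e7 J/mol).
KCAL_TO_AMU_A2_FS2 = 4.184e-4

#: Speed of light, cm/fs (for wavenumber axes).
C_CM_PER_FS = 2.99792458e-5

#: Hartree in kcal/mol.
HARTREE_KCAL = 627.509474

#: Hartree in cm^-1.
HARTREE_CM1 = 219474.6313632

#: Bohr radius in Å.
BOHR_A = 0.529177210903

#: 1 amu in electron masses.
AMU_ME = 1822.888486
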