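"""Physical constants and unit conversions.

Internal unit system: lengths in Å, energies in kcal/mol, charges in
elementary charge units (e), masses in amu, temperature in K.
"""

#: Coulomb conversion factor, kcal·Å/(mol·e²).  The value conventional in
#: biomolecular force fields; configurable where it matters.
COULOMB_CONSTANT = 332.0637

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL = 0.0019872041

#: Gas constant, cal/(mol·K) — entropy values are reported in cal/(mol·K).
R_CAL = 1.9872041

#: Second radiation constant h·c/k_B in cm·K; converts wavenumbers to
#: reduced vibrational temperatures x = c2 * nu_tilde / T.
C2_CM_K = 1.4387769

#: Converts a mass-weighted Hessian eigenvalue (kcal/mol/Å²/amu) to an
#: angular frequency squared in s⁻²:  4184 J/kcal / (1e-3 kg/amu · 1e-20 m²/Å²).
EIGVAL_TO_OMEGA_SQ = 4.184e26

#: Speed of light, cm/s.
C_LIGHT_CM = 2.99792458e10

#: Planck constant, J·s.
H_PLANCK = 6.62607015e-34

#: Boltzmann constant, J/K.
KB_SI = 1.380649e-23

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: amu in kg.
AMU_KG = 1.66053906660e-27

#: Standard pressure, Pa (1 atm).
P_STANDARD = 101325.0

#: Default analysis temperature, K.
T_DEFAULT = 300.0
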