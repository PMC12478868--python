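"""Physical constants and unit conversions.

Internal units throughout the package are fixed: energies in eV, lengths in
angstrom, charges in elementary charge units (e), dipoles in e*angstrom,
potentials in volts (eV/e) and fields in V/angstrom.  Inputs declared in
Hartree, Debye, nm or bohr are converted once at load time.
"""

# Coulomb constant in eV * angstrom / e^2 (package-wide electrostatics scale)
COULOMB_EV_ANG = 14.399645

# Boltzmann constant, eV/K (CODATA 2018)
BOLTZMANN_EV_K = 8.617333262e-5

# Absolute potential of the standard hydrogen electrode, volts
SHE_VOLTS = 4.281

# Unit conversions to internal units
HARTREE_TO_EV = 27.211386245988
DEBYE_TO_E_ANG = 0.2081943
NM_TO_ANG = 10.0
BOHR_TO_ANG = 0.529177210903

ENERGY_FACTORS = {"ev": 1.0, "hartree": HARTREE_TO_EV, "ha": HARTREE_TO_EV,
                  "au": HARTREE_TO_EV}
DIPOLE_FACTORS = {"e*angstrom": 1.0, "e_angstrom": 1.0, "eang": 1.0,
                  "debye": DEBYE_TO_E_ANG, "d": DEBYE_TO_E_ANG}
LENGTH_FACTORS = {"angstrom": 1.0, "a": 1.0, "ang": 1.0,
                  "nm": NM_TO_ANG, "bohr": BOHR_TO_ANG, "au": BOHR_TO_ANG}
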