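"""Physical constants in the package's working units (kcal/mol, Å, e, K)."""

#: Boltzmann constant, kcal/(mol K); kT at 310 K = 0.61597 kcal/mol.
K_BOLTZMANN_KCAL = 1.987e-3

#: Coulomb prefactor, kcal Å / (mol e^2).
COULOMB_CONSTANT_KCAL = 332.0636

#: Physiological simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0
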