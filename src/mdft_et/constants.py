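"""Physical constants of the fixed unit system (Å, kJ/mol, e, K)."""

#: Coulomb constant e²/(4πε₀) in kJ·Å·mol⁻¹·e⁻².
COULOMB = 1389.35457

#: Boltzmann constant in kJ·mol⁻¹·K⁻¹.
KB = 0.0083144621

#: Wigner lattice (cubic Ewald) self-interaction constant ξ_EW.
XI_EWALD = -2.837297

#: Bohr radii per Ångström, for Gaussian cube output.
BOHR_PER_ANGSTROM = 1.8897261246

#: Default cap on external potentials, in units of k_B·T.
DEFAULT_CAP_KT = 100.0
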