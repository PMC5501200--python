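description: >
  As reduced_c1_nobind but with the steeper asymmetric vessel pressures
  {DA: 1, PCV: -0.5, DLAV: 0.8}; the pressure field shapes the VEGFC
  gradient when sequestration is off.
geometry_variant: standard
half_domain: true
species: [VC]
C1_initial: 0.1
C1_constant: 0.1
pressures: asymmetric
diffusivity_mode: simplified
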