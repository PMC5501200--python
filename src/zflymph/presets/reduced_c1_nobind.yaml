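description: >
  Collagen fixed at 0.1 and VEGFC not interacting with it at all; the
  interstitial flow is free to redistribute VEGFC.
geometry_variant: standard
half_domain: true
species: [VC]
C1_initial: 0.1
C1_constant: 0.1
pressures: symmetric
diffusivity_mode: simplified
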