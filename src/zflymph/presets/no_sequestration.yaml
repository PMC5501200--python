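description: >
  Primary network with every VEGFC-collagen interaction switched off
  (the bound complex is removed); shows that matrix sequestration is what
  steepens the VEGFC gradient in the diffusion-dominant regime.
geometry_variant: standard
half_domain: true
species: [VC, M2, M2P, M2T2, T2, C1, MT1, MT1T2, MT1T2M2P]
# the bound complex VCC1 is absent, which switches off the whole
# VEGFC-collagen interaction (forward and reverse binding terms)
C1_initial: 1.0
pressures: symmetric
diffusivity_mode: simplified
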