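description: >
  Initial collagen reduced uniformly to 0.1 (marginally convection-
  dominant); VEGFC-collagen forward binding terms scaled x10 to keep the
  sequestration capacity fixed; no collagenolysis.
geometry_variant: standard
half_domain: true
species: [VC, C1, VCC1]
C1_initial: 0.1
binding_multiplier: 10.0
pressures: symmetric
diffusivity_mode: simplified
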