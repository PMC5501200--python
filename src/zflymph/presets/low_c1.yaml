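description: >
  Initial collagen 0.01 (overwhelmingly convection-dominant); binding
  terms x100; hindrance correction to the VEGFC diffusivity dropped
  (< 6% effect at this collagen level); no collagenolysis.
geometry_variant: standard
half_domain: true
species: [VC, C1, VCC1]
C1_initial: 0.01
binding_multiplier: 100.0
pressures: symmetric
diffusivity_mode: free
# convection-dominated: error control relaxed so the integrator is not
# pinned to the advective cell-transit time while the front crosses
rtol: 1.0e-4
atol: 1.0e-6
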