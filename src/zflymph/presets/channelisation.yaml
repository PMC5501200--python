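description: >
  Triply widened slice with constant MMP2 production, collagenolysis, the
  asymmetric pressure field and initial collagen 0.1: the flow/remodelling
  feedback carves a low-collagen, high-VEGFC corridor in the vessels'
  plane.
geometry_variant: widened
half_domain: true
species: [M2, VC, C1]
C1_initial: 0.1
constant_m2_production: 10.0
pressures: asymmetric
diffusivity_mode: simplified
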