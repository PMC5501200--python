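description: >
  MMP2 activation replaced by a constant LEC production rate of 10
  (nondimensional); proMMP2, TIMP2, MT1-MMP and their complexes dropped.
  Probes strong, spatially uniform collagenolysis.
geometry_variant: standard
half_domain: true
species: [M2, VC, C1, VCC1]
C1_initial: 1.0
constant_m2_production: 10.0
pressures: symmetric
diffusivity_mode: simplified
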