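description: >
  Full reaction network on the standard slice: VEGFC released from the DA,
  sequestered by collagen I; proMMP2/TIMP2 produced by the LEC; MMP2
  activated by the MT1-MMP cascade and degrading collagen I.
geometry_variant: standard
half_domain: true
species: [VC, M2, M2P, M2T2, T2, C1, VCC1, MT1, MT1T2, MT1T2M2P]
C1_initial: 1.0
pressures: symmetric
diffusivity_mode: simplified
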