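description: >
  Collagen fixed at 0.01 and VEGFC not interacting with it; the strong
  interstitial flow alone sets the VEGFC distribution.
geometry_variant: standard
half_domain: true
species: [VC]
C1_initial: 0.01
C1_constant: 0.01
pressures: symmetric
diffusivity_mode: free
rtol: 1.0e-4
atol: 1.0e-6
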