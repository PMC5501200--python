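# Methods

## Model

The trunk slice is treated as a two-dimensional porous medium: an
interstitial space (IS) of collagen I bathed in interstitial fluid, with
three circular vessel lumina excluded from it and one circular lymphatic
endothelial cell (LEC) embedded in it as a separate reactive subdomain.
The blood circulation drives a steady interstitial flow from the dorsal
aorta (high pressure) to the posterior cardinal vein and the dorsal
anastomotic vessel (both set to zero); the slice's outer faces and the
LEC surface are impermeable.  VEGFC is released at a constant rate on the
DA surface, diffuses with Ogston-type hindrance, is carried by the flow,
binds reversibly to collagen I (a 1:1 surrogate for matrix sequestration),
and degrades.  The LEC produces proMMP2 and TIMP2; membrane-type MT1-MMP,
smeared uniformly over the LEC disc, activates proMMP2 through the
ternary MT1·TIMP2·proMMP2 intermediate.  Mature MMP2 diffuses into the
interstitium, is inhibited reversibly by TIMP2 (primary scenario only),
and degrades collagen I by Michaelis–Menten kinetics.  Collagen sets both
the hydraulic conductivity (power law in the collagen mass fraction,
slope −2.70, intercept 10⁻¹⁴·¹⁸ in CGS hydraulic-conductivity units,
converted with a 1 cP reference viscosity) and the hindered diffusivity /
exclusion volume of every mobile species, closing two feedback loops:
degradation → conductivity → convection, and degradation → diffusivity.

Everything the solvers touch is nondimensional.  Scales: length
L = 434 µm (slice height), time τ = 12 h (the developmental window),
pressure P^DA = 0.1844 mmHg (mean of peak-systolic and end-diastolic
measurements), velocity U = κ(C_C1,s)·P^DA/(μL) = 1.371·10⁻⁴ µm/s so that
the Darcy drag group η₁ is exactly one at full collagen.  Concentration
scales pin the dimensionless production and binding groups to one:
C_C1,s = 3.50·10⁻⁴ M (the adult-tissue midpoint; the embryonic value
1.59·10⁻⁶ M is stored as an alternative initial condition),
C_MT1,s = 5.71·10⁻⁷ M for the whole MT1 pool, C_VC,s = R_DA^VC τ/L,
C_M2P,s = P_M2P τ, C_T2,s = P_T2 τ, C_M2,s = k_act τ C_MT1,0²,
C_M2T2,s = k_on^M2,T2 τ C_M2,s C_T2,s, C_VCC1,s = k_on^VC,C1 τ C_VC,s
C_C1,s.  Units live exclusively in `parameters.py` (fixed conversion
factors: 1 mmHg = 133.322 Pa = 1.35951 cmH₂O) and are stripped exactly
once when scales and groups are computed.

## Geometry

The slice measurements fix the rectangle and the circle diameters but not
the absolute dorsoventral position of the vessel stack, and they leave
the reading of the two inter-vessel distances (surface gap vs
centre-to-centre) open.  Both are package choices, made once:

* distances are read as **surface-to-surface** gaps.  Reason: the VEGFC
  decay length between PCV and DA produced by the model is ≈ 15 µm, and
  the documented ≈ thirtyfold concentration rise across that gap requires
  a ≈ 51 µm free path (e^(51/15) ≈ 30); a centre-to-centre reading leaves
  only 35 µm and a ≈ 10-fold rise.  The convention is switchable
  (`distance_convention="center"`).
* the PCV centre sits at ỹ = −0.275, which places the reference
  channelisation cut line ỹ = −0.23 inside the open PCV–LEC gap (the cut
  must not graze an exclusion) while keeping the whole stack inside the
  rectangle.  The anchor is configurable.

The LEC centre is the midpoint of the PCV and DA centres.  The widened
variant triples the width so the half-domain spans exactly x̃ ∈ [−0.15, 0].
All production runs use the symmetric half-domain (mirror symmetry about
x̃ = 0 with zero normal flux and velocity).

## Discretisation

**Meshing.**  A force-equilibrium (distmesh-type) generator relaxes a
graded point cloud on the signed-distance description of the domain,
retriangulating with Delaunay; points seeded on the circles are held
fixed, so the triangulation conforms to the vessel boundaries and to the
LEC interface, and the LEC disc is meshed and tagged as a subdomain.
Circle boundaries are polygonal (segment length = the local size knob).
Default sizes: 1.5 µm/434 on the circles grading to 5 µm/434 in the far
field (≈ 5,200 triangles on the half domain, ≈ 10,600 on the full
domain); a `resolution` multiplier scales both.  Meshes are validated on
construction: positive areas, minimum angle ≥ 20°, tagged boundary
lengths within 2 % of the analytic arcs, consistent subdomain
classification.  The generator is deterministic given a seed.

**Flow.**  With η₃ ≈ 1.5·10⁻¹¹ the Brinkman viscous correction is a
singular perturbation whose no-slip layers are ~√η₃ ≈ 4·10⁻⁶ of the
domain — physically nanometres — and cannot be resolved at any sensible
mesh, while a mixed discretisation at drag/viscosity ratios of 10¹¹ is
numerically meaningless.  The solver therefore discretises the Darcy
limit in primal form, div(κ̃ ∇P̃) = 0 with κ̃ = (C̃_C1 + η₂C̃_VCC1)^α
(linearised to C̃_C1^α in production runs), P1 elements, Dirichlet lumen
pressures and natural no-flux conditions elsewhere; the velocity
ũ = −κ̃∇P̃ is recovered per element.  Boundary fluxes are extracted from
the discrete residual and balance to machine precision.  The
finite-permeability (Robin) vessel conditions are implemented as an
option (`vessel_bc="permeable"`); at the measured dimensionless
permeabilities (~10¹⁴) they are indistinguishable from the Dirichlet
limit, which is why the Dirichlet form is the default.  Convergence is
verified at second order against a manufactured solution and an analytic
one-dimensional variable-conductivity profile.

**Transport.**  P1 elements with a lumped mass matrix on the same mesh.
proMMP2, MMP2 and TIMP2 are single continuous fields over IS ∪ LEC with a
discontinuous diffusivity (free-fluid λ₁ inside the LEC, hindered D̃ᵉᶠᶠ
outside) and ω ≡ 1 inside the LEC, which satisfies both interface
continuity conditions weakly.  VEGFC and MMP2·TIMP2 live on the IS
submesh with a natural no-flux condition at the LEC surface.  Immobile
species are pointwise ODEs at their subdomain's nodes; at interface
nodes the reaction rate of a shared field is the subdomain-lumped-mass
weighted blend of the IS and LEC rates.  The convective term is Galerkin
plus streamline-diffusion stabilisation with τ = ξ(Pe_h)·h/(2|a|),
ξ = min(Pe_h/3, 1); the stabilisation vanishes in pure-diffusion
configurations.  The DA influx enters as a boundary load with
lumped-edge-length weights, which makes the semidiscrete total-mass
balance exact (verified to 10⁻⁷ relative in the tests).

**Time integration.**  Adaptive variable-order BDF (scipy's
implementation) with maximum nondimensional step 0.02, first step 10⁻⁷
(the diffusive time across 1 µm for the fastest species is 2.1·10⁻⁷, and
the initially absent mobile species change fastest at the start), and an
analytic sparse Jacobian assembled from the frozen transport operator
plus the exact pointwise reaction Jacobian; the weak dependence of the
transport coefficients on collagen is neglected in the Jacobian, which
only affects Newton's convergence rate.  Default tolerances rtol = 10⁻⁵,
atol = 10⁻⁹, with a 10⁻¹⁶ absolute floor for MMP2·TIMP2 (its values sit
eight orders below its scale while its rate groups reach 10¹²).  The two
collagen-starved presets relax to rtol = 10⁻⁴, atol = 10⁻⁶ so the error
control is not pinned to the advective cell-transit time while the VEGFC
front crosses the domain.  Halving the maximum step changes the final
minimum collagen by < 10⁻⁵ relative.

The flow is re-solved at every right-hand-side evaluation whenever
collagen is a dynamic field (the fully coupled mode; a Darcy solve is a
few milliseconds, and a threshold-cached quasi-static mode — available
via `flow_refresh_rel_tol` — makes the ODE right-hand side discontinuous
inside Newton iterations and can stall the step-size control in the
strongly coupled scenarios).  When collagen is frozen the flow is solved
once.  Collagen entering the conductivity law is floored at 10⁻⁴ of its
scale purely to keep the power law finite against float noise.

Concentration undershoots below 10⁻⁸ (nondimensional) at checkpoints are
clipped to zero when fields are exported; undershoots above 10⁻² abort
the run.  The integrator itself never clips, so linear invariants are
preserved: the MT1 pool sums to one pointwise to ~10⁻¹⁴ over the whole
primary run.

## Scenario presets

Presets are YAML fixtures (`zflymph/presets/`); removing a species from a
preset removes every reaction it participates in, which is how the
reduced experiments zero entire groups of rate terms.  Kinetic overrides
are declarative: forward VEGFC–collagen binding multipliers (×10 at
C̃_C1(0) = 0.1, ×100 at 0.01) and the constant MMP2 production rate 10
replacing the activation cascade.  The asymmetric pressure set is
{DA: 1, PCV: −0.5, DLAV: 0.8} in DA-pressure units.  The collagen-starved
presets drop the hindrance correction to the VEGFC diffusivity (< 6 %
at C̃_C1 ≤ 0.1).

## Problem sizes

Default production resolution: ≈ 5,200 triangles / 2,900 nodes on the
half domain (≈ 20,000 unknowns for the full network), chosen from the
refinement study — the peak interstitial speed changes by < 5 % over the
last refinement doubling, and the final minimum collagen is
kinetics-limited and mesh-insensitive at this size.  A primary run takes
well under a minute on one core; the test suite runs the scenario
comparisons on an ≈ 1,900-triangle mesh, where every qualitative
conclusion is unchanged.

## Accuracy checks and known deviations

Independent oracles back every layer: hand-verified characteristic
scales and dimensionless groups (all published table entries reproduced
to 3 significant figures; one entry is published to a single figure and
is matched at that precision); a manufactured solution and an analytic
1-D profile for the flow (observed order 2.0); a radial Crank–Nicolson
reference for short-time VEGFC release (0.7 % agreement); a well-mixed
two-compartment ODE reduction of the full reaction network, which the
PDE solution tracks to ≈ 2 % in the near-uniform species.

Four published reference values are *not* reproduced, deliberately:

* **Peak interstitial speed / peak |ũ|Pe.**  At full collagen the
  nondimensional Darcy problem on this geometry has no free parameters;
  its peak speed is ≈ 19 velocity-scale units (0.0026 µm/s), insensitive
  to the vessel-stack placement and converged under refinement, whereas
  the reference computation reports ≈ 126 (0.0173 µm/s).  No layout
  consistent with the published dimensions produces the larger value (it
  would require a pressure sink ~5 µm from the DA surface).  The package
  reports its own converged value.
* **Minimum collagen 0.9991.**  The printed equations and parameters
  give 0.99969 at t̃ = 1 (collagen loss 3.1·10⁻⁴): the well-mixed ODE
  oracle, integrated at rtol 10⁻¹⁰, agrees with the PDE to 2·10⁻⁵, so
  the difference from the published 9·10⁻⁴ loss is not a discretisation
  artefact of this implementation.
* **First-order Ogston truncation within 2 %.**  The truncation error of
  1 − x versus e^(−x) at the VEGFC operating point x = λ₂√λ₃ ≈ 0.51 is
  18 % (3.2 % for TIMP2, the most favourable species); 2 % holds only for
  C̃_C1 ≲ 0.02.  Both forms are implemented; the simplified form is the
  production default for fidelity to the reference model, and the sweep
  documenting the actual agreement is part of the test suite.
* **Threefold asymmetric-pressure gradient.**  The faithful run gives a
  2.74-fold VEGFC drop from the PCV to the DA (time- and
  mesh-converged, with the correct orientation — VEGFC piles up against
  the PCV).  The shortfall from 3 tracks the peak-speed deviation above:
  a stronger flow steepens the convective gradient.

## What the model does and does not capture

The slice is an idealisation: stationary LEC, one DLAV standing for the
pair (its permeability doubled where permeabilities enter), no
intersegmental vessels, no pulsatility, no VEGFC processing or receptor
binding, no MT1-MMP shedding, matrix reduced to collagen I, and
parameters assembled from heterogeneous sources (several not measured in
fish embryos).  Passing tests therefore demonstrate internal consistency
of this model and its numerics — gradient shapes, dominance regimes,
feedback directions — not quantitative prediction for a real embryo.
The collagen-starved scenarios push the conductivity law far outside the
range of the data behind it; their flows (~0.5 mm/s) should be read as a
regime illustration, not physiology.
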