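"""Reactive transport of the species network on the meshed slice.

Mobile species obey nondimensional reaction-diffusion-convection equations
in the interstitial space and reaction-diffusion in the LEC disc; immobile
species (collagen I, its VEGFC complex, and the MT1-MMP pool) obey pointwise
ODEs.  proMMP2, MMP2 and TIMP2 are single continuous fields over the union
of both subdomains with a discontinuous diffusivity (free-fluid inside the
LEC, hindered outside), which realises the interface flux/concentration
continuity conditions weakly.

Discretisation: P1 finite elements with lumped mass; the convective term is
stabilised with streamline diffusion (disabled automatically when the cell
Peclet number is small).  Time integration is adaptive variable-order BDF
(scipy) with an analytic sparse Jacobian; default maximum nondimensional
step 0.02 and initial step 1e-7 — the transient when the initially absent
mobile species first permeate the geometry needs tight early control.

The interstitial flow is quasi-static: it is re-solved whenever the drag
field C~_C1^(-alpha) has drifted by more than a relative threshold since
the last solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .flow import (ConductivityLaw, FlowField, boundary_lumped_length,
                   dimensionless_mobility, p1_gradients, solve_flow,
                   DEFAULT_VESSEL_PRESSURES)
from .meshing import Mesh
from .parameters import DimensionlessGroups, MOBILE_SPECIES

__all__ = [
    "SPECIES_DOMAINS",
    "TransportConfig",
    "TransportSystem",
    "SimulationState",
    "Trajectory",
    "TransportError",
    "exclusion_fraction",
    "effective_diffusivity",
    "reaction_rates_IS",
    "reaction_rates_LEC",
    "boundary_condition_summary",
]


class TransportError(RuntimeError):
    pass


#: domain membership: where each species lives and whether it diffuses.
#: "both" species cross the LEC interface; "IS" mobile species see a no-flux
#: condition at the LEC surface; immobile species are pointwise ODEs.
SPECIES_DOMAINS: Dict[str, str] = {
    "M2P": "both", "M2": "both", "T2": "both",
    "VC": "IS", "M2T2": "IS",
    "C1": "IS_ode", "VCC1": "IS_ode",
    "MT1": "LEC_ode", "MT1T2": "LEC_ode", "MT1T2M2P": "LEC_ode",
}

DEFAULT_CHECKPOINTS = (0.25, 0.5, 0.75, 1.0)


# ---------------------------------------------------------------------------
# transport coefficients (Ogston hindrance and exclusion volume)
# ---------------------------------------------------------------------------


def exclusion_fraction(C_C1, C_VCC1, groups: DimensionlessGroups,
                       mode: str = "full"):
    """Fluid volume fraction omega available for diffusion.

    ``full``: omega = 1 - lam5*C~_C1 - lam6*C~_VCC1.  ``simplified`` returns
    omega implied by the first-order reciprocal 1/omega ~ 1 + lam5*C~_C1.
    Raises on nonpositive omega (collagen so dense nothing can diffuse).
    """
    C_C1 = np.asarray(C_C1, dtype=float)
    C_VCC1 = np.asarray(C_VCC1, dtype=float)
    if mode == "full":
        om = 1.0 - groups.lam["5"] * C_C1 - groups.lam["6"] * C_VCC1
    elif mode == "simplified":
        om = 1.0 / (1.0 + groups.lam["5"] * C_C1)
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    if np.any(om <= 0.0):
        raise TransportError("exclusion fraction omega <= 0: invalid state")
    return om


def effective_diffusivity(species: str, C_C1, C_VCC1,
                          groups: DimensionlessGroups,
                          mode: str = "simplified"):
    """Nondimensional effective diffusivity D~_eff of a mobile species.

    ``full``: the exponential Ogston form lam1*exp(-lam2*sqrt(lam3*C1 +
    lam4*VCC1)); ``simplified``: the first-order truncation
    lam1*(1 - lam2*sqrt(lam3*C1)); ``free``: lam1 alone (used in the
    collagen-starved scenario where the hindrance correction is < 6%).
    """
    lam1 = groups.lam_1[species]
    lam2 = groups.lam_2[species]
    C_C1 = np.asarray(C_C1, dtype=float)
    if mode == "full":
        arg = groups.lam["3"] * C_C1 + groups.lam["4"] * np.asarray(C_VCC1, dtype=float)
        return lam1 * np.exp(-lam2 * np.sqrt(np.maximum(arg, 0.0)))
    if mode == "simplified":
        return lam1 * (1.0 - lam2 * np.sqrt(np.maximum(groups.lam["3"] * C_C1, 0.0)))
    if mode == "free":
        return lam1 * np.ones_like(C_C1)
    raise ValueError(f"unknown diffusivity mode {mode!r}")


# ---------------------------------------------------------------------------
# reaction network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One elementary nondimensional reaction term.

    ``rate`` is a product of the listed reactant concentrations times
    ``prefactor``; each affected species gains ``stoich[species] * rate``
    (the stoichiometric factors differ per species because each equation is
    scaled by its own concentration scale).  ``michaelis`` marks the
    collagenolysis term, whose denominator K_M + C_C1s*C~_C1 is dimensional.
    """

    name: str
    domain: str                      # "IS" or "LEC"
    reactants: Tuple[str, ...]
    stoich: Mapping[str, float]
    prefactor: float = 1.0
    michaelis: bool = False


def build_reactions(groups: DimensionlessGroups,
                    binding_multiplier: float = 1.0,
                    constant_m2_production: Optional[float] = None
                    ) -> List[Reaction]:
    """The reaction network, optionally with scenario overrides.

    ``binding_multiplier`` scales the forward VEGFC-collagen binding terms
    (the x10 / x100 kinetic overrides of the reduced-collagen experiments);
    ``constant_m2_production`` replaces the MT1-MMP activation mechanism
    with a constant LEC production rate for MMP2.
    """
    lam = groups.lam
    mb = binding_multiplier
    rxns = [
        Reaction("deg_M2P", "IS", ("M2P",), {"M2P": -lam["11"]}),
        Reaction("bind_M2_T2", "IS", ("M2", "T2"),
                 {"M2": -lam["13"], "T2": -lam["19"], "M2T2": +1.0}),
        Reaction("unbind_M2_T2", "IS", ("M2T2",),
                 {"M2": +lam["14"], "T2": +lam["20"], "M2T2": -lam["23"]}),
        Reaction("deg_M2", "IS", ("M2",), {"M2": -lam["15"]}),
        Reaction("deg_T2", "IS", ("T2",), {"T2": -lam["21"]}),
        Reaction("deg_M2T2", "IS", ("M2T2",), {"M2T2": -lam["24"]}),
        Reaction("bind_VC_C1", "IS", ("VC", "C1"),
                 {"VC": -mb * lam["25"], "C1": -mb * lam["29"], "VCC1": +mb},
                 ),
        Reaction("unbind_VC_C1", "IS", ("VCC1",),
                 {"VC": +lam["26"], "C1": +lam["30"], "VCC1": -lam["32"]}),
        Reaction("deg_VC", "IS", ("VC",), {"VC": -lam["27"]}),
        Reaction("collagenolysis", "IS", ("M2", "C1"),
                 {"C1": -lam["28"]}, michaelis=True),
        Reaction("prod_M2P", "LEC", (), {"M2P": +1.0}),
        Reaction("prod_T2", "LEC", (), {"T2": +1.0}),
        Reaction("bind_MT1_T2", "LEC", ("MT1", "T2"),
                 {"MT1": -lam["33"], "T2": -lam["17"], "MT1T2": +lam["35"]}),
        Reaction("unbind_MT1_T2", "LEC", ("MT1T2",),
                 {"MT1": +lam["34"], "T2": +lam["18"], "MT1T2": -lam["36"]}),
        Reaction("bind_MT1T2_M2P", "LEC", ("MT1T2", "M2P"),
                 {"MT1T2": -lam["37"], "M2P": -lam["9"], "MT1T2M2P": +lam["40"]}),
        Reaction("unbind_MT1T2_M2P", "LEC", ("MT1T2M2P",),
                 {"MT1T2": +lam["38"], "M2P": +lam["10"], "MT1T2M2P": -lam["41"]}),
    ]
    if constant_m2_production is None:
        rxns.append(Reaction("activate_M2", "LEC", ("MT1T2M2P", "MT1"),
                             {"M2": +1.0, "MT1T2": +lam["39"],
                              "MT1T2M2P": -lam["42"]}))
    else:
        rxns.append(Reaction("prod_M2_const", "LEC", (),
                             {"M2": +float(constant_m2_production)}))
    return rxns


def _restrict_reactions(rxns: Sequence[Reaction],
                        species: Sequence[str]) -> List[Reaction]:
    """Keep only reactions where every participating species is active.

    Dropping a species from a scenario removes the whole interaction it
    takes part in (e.g. removing the VEGFC-collagen complex switches off
    both the forward and reverse binding terms), matching how the reduced
    numerical experiments zero entire lambda sets.
    """
    active = set(species)
    out = []
    for r in rxns:
        if not set(r.reactants) <= active:
            continue
        if not set(r.stoich) <= active:
            continue
        out.append(r)
    return out


def _eval_reactions(rxns: Sequence[Reaction], conc: Mapping[str, np.ndarray],
                    n: int, groups: DimensionlessGroups, domain: str
                    ) -> Dict[str, np.ndarray]:
    """Pointwise net production rates for every species, one domain."""
    rates: Dict[str, np.ndarray] = {}
    for r in rxns:
        if r.domain != domain:
            continue
        rate = np.full(n, r.prefactor)
        for s in r.reactants:
            rate = rate * conc[s]
        if r.michaelis:
            rate = rate / (groups.K_M + groups.C_C1_s * conc["C1"])
        for s, coef in r.stoich.items():
            if s in rates:
                rates[s] = rates[s] + coef * rate
            else:
                rates[s] = coef * rate
    return rates


def reaction_rates_IS(conc: Mapping[str, float | np.ndarray],
                      groups: DimensionlessGroups,
                      binding_multiplier: float = 1.0) -> Dict[str, np.ndarray]:
    """The interstitial-space net rates for a pointwise state."""
    conc = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in conc.items()}
    n = max(len(v) for v in conc.values())
    rxns = _restrict_reactions(
        build_reactions(groups, binding_multiplier), list(conc))
    return _eval_reactions(rxns, conc, n, groups, "IS")


def reaction_rates_LEC(conc: Mapping[str, float | np.ndarray],
                       groups: DimensionlessGroups,
                       constant_m2_production: Optional[float] = None
                       ) -> Dict[str, np.ndarray]:
    """The LEC net rates for a pointwise state."""
    conc = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in conc.items()}
    n = max(len(v) for v in conc.values())
    rxns = _restrict_reactions(
        build_reactions(groups, 1.0, constant_m2_production), list(conc))
    return _eval_reactions(rxns, conc, n, groups, "LEC")


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransportConfig:
    """Scenario-level switches for one transport run."""

    species: Tuple[str, ...]
    C1_initial: float = 1.0
    #: collagen value used by flow/coefficients when C1 is not a state
    C1_constant: Optional[float] = None
    diffusivity_mode: str = "simplified"     # simplified | full | free
    exclusion_mode: str = "simplified"       # pairs with the diffusive flux form
    binding_multiplier: float = 1.0
    constant_m2_production: Optional[float] = None
    influx_scale: float = 1.0                # multiplies lambda_DA_VC = 1
    vessel_pressures: Mapping[str, float] = None
    conductivity_mode: str = "linearised"
    flow_enabled: bool = True
    #: None -> fully coupled (flow re-solved at every evaluation, smooth in
    #: the state, required when collagen evolves); a float -> quasi-static
    #: caching, refreshed when the drag field drifts by this relative amount
    flow_refresh_rel_tol: Optional[float] = None
    supg: bool = True
    max_step: float = 0.02
    first_step: float = 1e-7
    rtol: float = 1e-5
    atol_scale: float = 1e-9
    negativity_clip: float = 1e-8

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if self.vessel_pressures is None:
            object.__setattr__(self, "vessel_pressures",
                               dict(DEFAULT_VESSEL_PRESSURES))
        for s in self.species:
            if s not in SPECIES_DOMAINS:
                raise TransportError(f"unknown species {s!r}")
        if "C1" not in self.species and self.C1_constant is None:
            object.__setattr__(self, "C1_constant", self.C1_initial)


@dataclass
class SimulationState:
    """Nodal concentration fields and the current flow at one time point."""

    t: float
    fields: Dict[str, np.ndarray]     # local arrays per species (field node sets)
    flow: Optional[FlowField] = None

    def clipped(self, clip: float = 1e-8) -> Dict[str, np.ndarray]:
        """Fields with sub-threshold negative undershoots set to zero."""
        out = {}
        for k, v in self.fields.items():
            w = v.copy()
            w[(w < 0) & (w > -clip)] = 0.0
            out[k] = w
        return out


@dataclass
class Trajectory:
    times: np.ndarray
    states: List[SimulationState]
    system: "TransportSystem"
    n_flow_solves: int
    solver_report: dict

    def state_at(self, t: float) -> SimulationState:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]


def boundary_condition_summary(config: TransportConfig) -> Dict[str, Dict[str, str]]:
    """Human/machine-readable boundary-condition table for one run."""
    out: Dict[str, Dict[str, str]] = {}
    for s in config.species:
        dom = SPECIES_DOMAINS[s]
        if dom.endswith("_ode"):
            continue
        bc = {"outer": "no-flux", "PCV": "no-flux", "DLAV": "no-flux",
              "symmetry": "no-flux"}
        bc["DA"] = (f"constant influx {config.influx_scale:g}"
                    if s == "VC" else "no-flux")
        bc["LEC"] = ("flux and concentration continuity" if dom == "both"
                     else "no-flux")
        out[s] = bc
    return out


# ---------------------------------------------------------------------------
# the assembled transport system
# ---------------------------------------------------------------------------


class TransportSystem:
    """Semi-discrete transport operator on a tagged mesh.

    Builds the per-field node sets, lumped masses, diffusion/convection
    operators and the reaction network, exposes ``rhs``/``jac`` for the BDF
    integrator, and runs :meth:`advance`.
    """

    def __init__(self, mesh: Mesh, groups: DimensionlessGroups,
                 config: TransportConfig):
        self.mesh = mesh
        self.groups = groups
        self.config = config
        self.law = ConductivityLaw.from_groups(groups,
                                               mode=config.conductivity_mode)
        self._setup_topology()
        self._setup_fields()
        self.reactions = _restrict_reactions(
            build_reactions(groups, config.binding_multiplier,
                            config.constant_m2_production),
            config.species)
        self._flow: Optional[FlowField] = None
        self._flow_drag: Optional[np.ndarray] = None
        self.n_flow_solves = 0

    # -- mesh topology ------------------------------------------------------
    def _setup_topology(self):
        mesh = self.mesh
        pts = mesh.points
        self.n_nodes = mesh.n_points
        self.is_tris = mesh.triangles[mesh.tri_region == 0]
        self.lec_tris = mesh.triangles[mesh.tri_region == 1]
        self.g_is, self.area_is = p1_gradients(pts, self.is_tris)
        if len(self.lec_tris):
            self.g_lec, self.area_lec = p1_gradients(pts, self.lec_tris)
        else:
            self.g_lec = np.zeros((0, 3, 2))
            self.area_lec = np.zeros(0)
        self.is_nodes = np.unique(self.is_tris)
        self.lec_nodes = (np.unique(self.lec_tris) if len(self.lec_tris)
                          else np.array([], dtype=int))
        # lumped masses per subdomain (used for interface-weighted reactions)
        self.mass_is = np.zeros(self.n_nodes)
        self.mass_lec = np.zeros(self.n_nodes)
        for k in range(3):
            np.add.at(self.mass_is, self.is_tris[:, k], self.area_is / 3.0)
            if len(self.lec_tris):
                np.add.at(self.mass_lec, self.lec_tris[:, k], self.area_lec / 3.0)
        self.mass_total = self.mass_is + self.mass_lec
        # characteristic element size for streamline stabilisation
        self.h_is = np.sqrt(2.0 * self.area_is)
        # DA influx weights (nondimensional arc length per node)
        self.da_weights = boundary_lumped_length(
            mesh.boundary_edges["DA"], pts, self.n_nodes)

    def _setup_fields(self):
        cfg = self.config
        self.fields: List[str] = list(cfg.species)
        self.field_nodes: Dict[str, np.ndarray] = {}
        self.offsets: Dict[str, int] = {}
        off = 0
        for s in self.fields:
            dom = SPECIES_DOMAINS[s]
            if dom == "both":
                nodes = np.arange(self.n_nodes)
            elif dom in ("IS", "IS_ode"):
                nodes = self.is_nodes
            else:
                nodes = self.lec_nodes
            if len(nodes) == 0:
                raise TransportError(f"species {s} has an empty node set")
            self.field_nodes[s] = nodes
            self.offsets[s] = off
            off += len(nodes)
        self.n_dof = off
        # local index of each global node per field (-1 if absent)
        self.loc: Dict[str, np.ndarray] = {}
        for s in self.fields:
            lut = -np.ones(self.n_nodes, dtype=int)
            lut[self.field_nodes[s]] = np.arange(len(self.field_nodes[s]))
            self.loc[s] = lut
        # per-field lumped mass (union-domain mass for 'both' species)
        self.field_mass: Dict[str, np.ndarray] = {}
        for s in self.fields:
            dom = SPECIES_DOMAINS[s]
            if dom == "both":
                m = self.mass_total[self.field_nodes[s]]
            elif dom == "IS":
                m = self.mass_is[self.field_nodes[s]]
            else:
                m = None  # pointwise ODE, no mass matrix
            self.field_mass[s] = m

    # -- state packing ------------------------------------------------------
    def pack(self, fields: Mapping[str, np.ndarray]) -> np.ndarray:
        y = np.zeros(self.n_dof)
        for s in self.fields:
            o = self.offsets[s]
            y[o:o + len(self.field_nodes[s])] = fields[s]
        return y

    def unpack(self, y: np.ndarray) -> Dict[str, np.ndarray]:
        out = {}
        for s in self.fields:
            o = self.offsets[s]
            out[s] = y[o:o + len(self.field_nodes[s])]
        return out

    def initial_state(self) -> np.ndarray:
        fields = {}
        for s in self.fields:
            n = len(self.field_nodes[s])
            if s == "C1":
                fields[s] = np.full(n, self.config.C1_initial)
            elif s == "MT1":
                fields[s] = np.ones(n)
            else:
                fields[s] = np.zeros(n)
        return self.pack(fields)

    # -- global nodal views --------------------------------------------------
    def global_field(self, s: str, local: np.ndarray, fill: float = 0.0
                     ) -> np.ndarray:
        v = np.full(self.n_nodes, fill)
        v[self.field_nodes[s]] = local
        return v

    def _c1_global(self, fields: Mapping[str, np.ndarray]) -> np.ndarray:
        if "C1" in self.fields:
            return self.global_field("C1", fields["C1"])
        return np.full(self.n_nodes, float(self.config.C1_constant))

    def _vcc1_global(self, fields) -> np.ndarray:
        if "VCC1" in self.fields:
            return self.global_field("VCC1", fields["VCC1"])
        return np.zeros(self.n_nodes)

    # -- quasi-static flow ---------------------------------------------------
    def current_flow(self, fields) -> Optional[FlowField]:
        if not self.config.flow_enabled:
            return None
        C1 = self._c1_global(fields)
        if self._flow is not None:
            if "C1" not in self.fields:
                return self._flow          # collagen frozen: one solve suffices
            tol = self.config.flow_refresh_rel_tol
            if tol is not None:
                drag = dimensionless_mobility(
                    np.maximum(C1[self.is_tris].mean(axis=1), 1e-12), 0.0,
                    self.law)
                rel = np.max(np.abs(drag - self._flow_drag)
                             / np.maximum(np.abs(self._flow_drag), 1e-300))
                if rel <= tol:
                    return self._flow
        # collagen drifts below ~1e-4 of its scale only through float noise;
        # floor it so the conductivity power law stays finite
        self._flow = solve_flow(self.mesh, np.maximum(C1, 1e-4), self.groups,
                                vessel_pressures=self.config.vessel_pressures,
                                law=self.law,
                                C_VCC1_nodal=self._vcc1_global(fields))
        self._flow_drag = dimensionless_mobility(
            np.maximum(C1[self.is_tris].mean(axis=1), 1e-4), 0.0, self.law)
        self.n_flow_solves += 1
        return self._flow

    # -- semidiscrete right-hand side ---------------------------------------
    def _diffusive_divergence(self, s: str, c_global: np.ndarray,
                              C1: np.ndarray, VCC1: np.ndarray) -> np.ndarray:
        """Nodal residual of -int grad(v).F_diff, F per the configured mode."""
        cfg = self.config
        out = np.zeros(self.n_nodes)
        # interstitial part
        tris, g, area = self.is_tris, self.g_is, self.area_is
        c_e = c_global[tris]
        C1_e = C1[tris]
        D = effective_diffusivity(s, C1_e.mean(axis=1),
                                  VCC1[tris].mean(axis=1),
                                  self.groups, cfg.diffusivity_mode)
        grad_c = np.einsum("eik,ei->ek", g, c_e)
        if cfg.diffusivity_mode == "free":
            flux = D[:, None] * grad_c
        elif cfg.exclusion_mode == "simplified":
            # grad(C (1 + lam5 C1)) = (1+lam5 C1) grad C + lam5 C grad C1
            lam5 = self.groups.lam["5"]
            grad_c1 = np.einsum("eik,ei->ek", g, C1_e)
            fac = 1.0 + lam5 * C1_e.mean(axis=1)
            flux = D[:, None] * (fac[:, None] * grad_c
                                 + lam5 * c_e.mean(axis=1)[:, None] * grad_c1)
        else:
            # full form: grad(C/omega)
            lam5, lam6 = self.groups.lam["5"], self.groups.lam["6"]
            VCC1_e = VCC1[tris]
            om = 1.0 - lam5 * C1_e.mean(axis=1) - lam6 * VCC1_e.mean(axis=1)
            if np.any(om <= 0):
                raise TransportError("omega <= 0 during assembly")
            grad_c1 = np.einsum("eik,ei->ek", g, C1_e)
            grad_vcc1 = np.einsum("eik,ei->ek", g, VCC1_e)
            grad_om = -(lam5 * grad_c1 + lam6 * grad_vcc1)
            flux = D[:, None] * (grad_c / om[:, None]
                                 - (c_e.mean(axis=1) / om**2)[:, None] * grad_om)
        contrib = -np.einsum("eik,ek->ei", g, flux) * area[:, None]
        np.add.at(out, tris, contrib)
        # LEC part: free diffusion
        if SPECIES_DOMAINS[s] == "both" and len(self.lec_tris):
            lam1 = self.groups.lam_1[s]
            grad_c = np.einsum("eik,ei->ek", self.g_lec, c_global[self.lec_tris])
            contrib = -lam1 * np.einsum("eik,ek->ei", self.g_lec, grad_c) \
                * self.area_lec[:, None]
            np.add.at(out, self.lec_tris, contrib)
        return out

    def _convective_divergence(self, s: str, c_global: np.ndarray,
                               flow: FlowField, C1: np.ndarray,
                               VCC1: np.ndarray) -> np.ndarray:
        """Nodal residual of the (stabilised) convection term, IS only."""
        lam7 = self.groups.lam["7"]
        a = lam7 * flow.u_elem[self.mesh.tri_region == 0]   # (ne, 2)
        tris, g, area = self.is_tris, self.g_is, self.area_is
        c_e = c_global[tris]
        out = np.zeros(self.n_nodes)
        # Galerkin: +int grad(v).(a C)  (= -int v div(aC) with no-flux bdry)
        adotg = np.einsum("ek,eik->ei", a, g)               # a . grad N_i
        contrib = adotg * (area * c_e.mean(axis=1))[:, None]
        np.add.at(out, tris, contrib)
        if self.config.supg:
            D = effective_diffusivity(s, C1[tris].mean(axis=1),
                                      VCC1[tris].mean(axis=1),
                                      self.groups, self.config.diffusivity_mode)
            speed = np.hypot(a[:, 0], a[:, 1])
            peh = speed * self.h_is / np.maximum(2.0 * D, 1e-300)
            xi = np.minimum(peh / 3.0, 1.0)
            tau = np.where(speed > 0, xi * self.h_is / np.maximum(2 * speed, 1e-300), 0.0)
            a_grad_c = np.einsum("ek,ek->e", a,
                                 np.einsum("eik,ei->ek", g, c_e))
            contrib = -adotg * (tau * area * a_grad_c)[:, None]
            np.add.at(out, tris, contrib)
        return out

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        fields = self.unpack(y)
        C1 = self._c1_global(fields)
        VCC1 = self._vcc1_global(fields)
        flow = self.current_flow(fields)
        conc_global = {s: self.global_field(s, fields[s]) for s in self.fields}

        dydt = np.zeros_like(y)
        # transport for mobile species
        for s in self.fields:
            dom = SPECIES_DOMAINS[s]
            if dom.endswith("_ode"):
                continue
            r = self._diffusive_divergence(s, conc_global[s], C1, VCC1)
            if flow is not None:
                r += self._convective_divergence(s, conc_global[s], flow,
                                                 C1, VCC1)
            if s == "VC":
                r += self.config.influx_scale * self.da_weights
            o = self.offsets[s]
            nodes = self.field_nodes[s]
            dydt[o:o + len(nodes)] = r[nodes] / self.field_mass[s]

        # reactions (interface nodes get the subdomain-mass-weighted blend)
        rates_is = _eval_reactions(self.reactions, conc_global, self.n_nodes,
                                   self.groups, "IS")
        rates_lec = _eval_reactions(self.reactions, conc_global, self.n_nodes,
                                    self.groups, "LEC")
        for s in self.fields:
            o = self.offsets[s]
            nodes = self.field_nodes[s]
            dom = SPECIES_DOMAINS[s]
            ris = rates_is.get(s)
            rlec = rates_lec.get(s)
            if dom == "both":
                num = np.zeros(self.n_nodes)
                if ris is not None:
                    num += self.mass_is * ris
                if rlec is not None:
                    num += self.mass_lec * rlec
                dydt[o:o + len(nodes)] += (num / self.mass_total)[nodes]
            elif dom in ("IS", "IS_ode"):
                if ris is not None:
                    dydt[o:o + len(nodes)] += ris[nodes]
            else:
                if rlec is not None:
                    dydt[o:o + len(nodes)] += rlec[nodes]
        return dydt

    # -- Jacobian ------------------------------------------------------------
    def _transport_matrix(self, s: str, C1: np.ndarray, VCC1: np.ndarray,
                          flow: Optional[FlowField]) -> sp.csr_matrix:
        """Sparse nodal operator L such that (transport rhs) ~ L c (frozen
        coefficients; the weak dependence of D~_eff and omega on C1 is
        neglected here, which only affects Newton convergence rate)."""
        n = self.n_nodes
        cfg = self.config
        tris, g, area = self.is_tris, self.g_is, self.area_is
        D = effective_diffusivity(s, C1[tris].mean(axis=1),
                                  VCC1[tris].mean(axis=1),
                                  self.groups, cfg.diffusivity_mode)
        if cfg.diffusivity_mode == "free":
            coeff = D
            ke = -np.einsum("eik,ejk->eij", g, g) * (coeff * area)[:, None, None]
        elif cfg.exclusion_mode == "simplified":
            lam5 = self.groups.lam["5"]
            fac = 1.0 + lam5 * C1[tris].mean(axis=1)
            grad_c1 = np.einsum("eik,ei->ek", g, C1[tris])
            ke = -np.einsum("eik,ejk->eij", g, g) \
                * (D * fac * area)[:, None, None]
            # lam5 * C grad C1 part: C is the element mean
            gi_dot_gc1 = np.einsum("eik,ek->ei", g, grad_c1)
            ke -= (D * lam5 * area / 3.0)[:, None, None] \
                * gi_dot_gc1[:, :, None] * np.ones((1, 1, 3))
        else:
            lam5, lam6 = self.groups.lam["5"], self.groups.lam["6"]
            om = 1.0 - lam5 * C1[tris].mean(axis=1) - lam6 * VCC1[tris].mean(axis=1)
            grad_om = -(lam5 * np.einsum("eik,ei->ek", g, C1[tris])
                        + lam6 * np.einsum("eik,ei->ek", g, VCC1[tris]))
            ke = -np.einsum("eik,ejk->eij", g, g) \
                * (D / om * area)[:, None, None]
            gi_dot_gom = np.einsum("eik,ek->ei", g, grad_om)
            ke += (D / om**2 * area / 3.0)[:, None, None] \
                * gi_dot_gom[:, :, None] * np.ones((1, 1, 3))
        if flow is not None:
            lam7 = self.groups.lam["7"]
            a = lam7 * flow.u_elem[self.mesh.tri_region == 0]
            adotg = np.einsum("ek,eik->ei", a, g)
            ke += (area / 3.0)[:, None, None] * adotg[:, :, None] \
                * np.ones((1, 1, 3))
            if cfg.supg:
                speed = np.hypot(a[:, 0], a[:, 1])
                peh = speed * self.h_is / np.maximum(2.0 * D, 1e-300)
                xi = np.minimum(peh / 3.0, 1.0)
                tau = np.where(speed > 0,
                               xi * self.h_is / np.maximum(2 * speed, 1e-300), 0.0)
                ke -= (tau * area)[:, None, None] \
                    * adotg[:, :, None] * adotg[:, None, :]
        rows = np.repeat(tris, 3, axis=1).ravel()
        cols = np.tile(tris, (1, 3)).ravel()
        data = ke.ravel()
        if SPECIES_DOMAINS[s] == "both" and len(self.lec_tris):
            lam1 = self.groups.lam_1[s]
            ke2 = -lam1 * np.einsum("eik,ejk->eij", self.g_lec, self.g_lec) \
                * self.area_lec[:, None, None]
            rows = np.concatenate([rows, np.repeat(self.lec_tris, 3, axis=1).ravel()])
            cols = np.concatenate([cols, np.tile(self.lec_tris, (1, 3)).ravel()])
            data = np.concatenate([data, ke2.ravel()])
        return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def jac(self, t: float, y: np.ndarray) -> sp.csr_matrix:
        fields = self.unpack(y)
        C1 = self._c1_global(fields)
        VCC1 = self._vcc1_global(fields)
        flow = self.current_flow(fields)
        conc_global = {s: self.global_field(s, fields[s]) for s in self.fields}

        blocks: Dict[Tuple[str, str], sp.coo_matrix] = {}

        def add_block(sa: str, sb: str, rows_g, cols_g, vals):
            la = self.loc[sa][rows_g]
            lb = self.loc[sb][cols_g]
            ok = (la >= 0) & (lb >= 0)
            m = sp.coo_matrix((np.asarray(vals)[ok],
                               (la[ok] + self.offsets[sa],
                                lb[ok] + self.offsets[sb])),
                              shape=(self.n_dof, self.n_dof))
            blocks[(sa, sb)] = blocks.get((sa, sb), 0) + m

        # transport blocks (divided by the per-field lumped mass)
        for s in self.fields:
            if SPECIES_DOMAINS[s].endswith("_ode"):
                continue
            L = self._transport_matrix(s, C1, VCC1, flow).tocoo()
            nodes = self.field_nodes[s]
            minv = np.zeros(self.n_nodes)
            minv[nodes] = 1.0 / self.field_mass[s]
            add_block(s, s, L.row, L.col, L.data * minv[L.row])

        # reaction Jacobian: d(stoich*rate)/d(reactant), pointwise
        all_nodes = np.arange(self.n_nodes)
        for r in self.reactions:
            if r.domain == "IS":
                wfrac = np.where(self.mass_total > 0,
                                 self.mass_is / self.mass_total, 0.0)
                dom_nodes_ode = self.is_nodes
            else:
                wfrac = np.where(self.mass_total > 0,
                                 self.mass_lec / self.mass_total, 0.0)
                dom_nodes_ode = self.lec_nodes
            base = np.full(self.n_nodes, r.prefactor)
            for sr in r.reactants:
                base = base * conc_global[sr]
            if r.michaelis:
                den = self.groups.K_M + self.groups.C_C1_s * conc_global["C1"]
                base = base / den
            for sb in set(r.reactants):
                # d rate / d C_sb
                drate = np.full(self.n_nodes, r.prefactor)
                for sr in r.reactants:
                    if sr != sb:
                        drate = drate * conc_global[sr]
                if r.michaelis:
                    den = self.groups.K_M + self.groups.C_C1_s * conc_global["C1"]
                    if sb == "C1":
                        # d/dC1 [M2*C1/den] = M2*(den - C1*C_C1s)/den^2
                        drate = (conc_global["M2"] * r.prefactor
                                 * (den - self.groups.C_C1_s * conc_global["C1"])
                                 / den**2)
                    else:
                        drate = drate / den
                for sa, coef in r.stoich.items():
                    dom_a = SPECIES_DOMAINS[sa]
                    if dom_a == "both":
                        w = wfrac
                        rows = all_nodes
                    elif dom_a.endswith("_ode"):
                        w = np.ones(self.n_nodes)
                        rows = dom_nodes_ode
                    else:
                        w = np.ones(self.n_nodes)
                        rows = self.field_nodes[sa]
                    vals = coef * drate[rows] * w[rows]
                    add_block(sa, sb, rows, rows, vals)

        J = sp.coo_matrix((self.n_dof, self.n_dof))
        for m in blocks.values():
            J = J + m
        return J.tocsr()

    # -- time integration ----------------------------------------------------
    def advance(self, t_end: float = 1.0,
                checkpoints: Sequence[float] = DEFAULT_CHECKPOINTS,
                y0: Optional[np.ndarray] = None) -> Trajectory:
        """Integrate the system from the standard initial state to t_end."""
        cfg = self.config
        if y0 is None:
            y0 = self.initial_state()
        t_eval = np.unique(np.concatenate([[0.0], np.asarray(checkpoints,
                                                             dtype=float),
                                           [t_end]]))
        t_eval = t_eval[t_eval <= t_end + 1e-12]
        atol = np.full(self.n_dof, cfg.atol_scale)
        # the M2.T2 complex sits ~8 orders below its scale while its rate
        # constants reach ~1e12: it needs a far tighter absolute floor
        for s in self.fields:
            if s == "M2T2":
                o = self.offsets[s]
                atol[o:o + len(self.field_nodes[s])] = 1e-16
        sol = solve_ivp(self.rhs, (0.0, t_end), y0, method="BDF",
                        t_eval=t_eval, jac=self.jac,
                        max_step=cfg.max_step, first_step=cfg.first_step,
                        rtol=cfg.rtol, atol=atol)
        if not sol.success:
            raise TransportError(f"BDF integration failed: {sol.message}")
        states = []
        for k, t in enumerate(sol.t):
            fields = self.unpack(sol.y[:, k])
            worst = min((float(v.min()) for v in fields.values()), default=0.0)
            if worst < -1e-2:
                raise TransportError(
                    f"large negative concentration ({worst:.3e}) at t={t}")
            states.append(SimulationState(t=float(t),
                                          fields={k2: v.copy() for k2, v
                                                  in fields.items()},
                                          flow=self._flow))
        report = dict(nfev=int(sol.nfev), njev=int(sol.njev),
                      nlu=int(sol.nlu), n_steps=len(sol.t),
                      message=str(sol.message))
        return Trajectory(times=sol.t, states=states, system=self,
                          n_flow_solves=self.n_flow_solves,
                          solver_report=report)
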