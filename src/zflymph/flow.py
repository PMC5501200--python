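"""Interstitial flow on the trunk slice.

The momentum balance in the interstitial space is Brinkman's equation with a
collagen-dependent drag.  After nondimensionalisation with the velocity
scale chosen so the drag group eta_1 = 1, the viscous correction carries the
prefactor eta_3 ~ 1.5e-11: the flow is deep in the Darcy regime, and the
no-slip layers the Brinkman term would resolve are of nondimensional width
~sqrt(eta_3 * kappa~), i.e. far below any feasible mesh size.  The solver
therefore discretises the Darcy limit in primal form,

    div( kappa~ grad P~ ) = 0,      u~ = -kappa~ grad P~,

with the dimensionless mobility kappa~ = (C~_C1 + eta_2 C~_VCC1)^alpha
(or C~_C1^alpha in the linearised mode used by the simulations), Dirichlet
pressures on the vessel lumina (the leaky-vessel limit), and natural
no-flux conditions on the outer walls, the LEC surface and the symmetry
line.  Linear (P1) elements; the velocity is recovered elementwise.

Pressures are handled in units of the DA pressure (P~); the "simulated
pressure" P~s = P~/eta_3 of the reference computation is available on the
result object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh, VESSEL_TAGS
from .parameters import DimensionlessGroups, conductivity_constants

__all__ = [
    "ConductivityLaw",
    "FlowField",
    "FlowSolverError",
    "SingularConductivityError",
    "specific_conductivity",
    "dimensionless_mobility",
    "solve_flow",
    "solve_darcy",
    "DEFAULT_VESSEL_PRESSURES",
    "ASYMMETRIC_VESSEL_PRESSURES",
]


class FlowSolverError(RuntimeError):
    pass


class SingularConductivityError(ValueError):
    """Total collagen vanished somewhere: the conductivity law diverges."""


#: vessel pressures in units of the DA pressure
DEFAULT_VESSEL_PRESSURES: Dict[str, float] = {"DA": 1.0, "PCV": 0.0, "DLAV": 0.0}
#: steeper, asymmetric field of the convection experiments
ASYMMETRIC_VESSEL_PRESSURES: Dict[str, float] = {"DA": 1.0, "PCV": -0.5, "DLAV": 0.8}


@dataclass(frozen=True)
class ConductivityLaw:
    """kappa = beta * (collagen mass fraction)^alpha, from a log-log fit.

    ``mode`` selects whether VEGFC-bound collagen contributes to the mass
    fraction ("full") or is dropped ("linearised", the simulated model).
    """

    alpha: float
    beta: float                  # cm^2
    mass_fraction_scale: float   # M_C1 * C_C1_s, the mass fraction at C~_C1 = 1
    eta_2: float                 # C_VCC1_s / C_C1_s
    mode: str = "linearised"

    @classmethod
    def from_groups(cls, groups: DimensionlessGroups, mode: str = "linearised",
                    M_C1: float = 300.0) -> "ConductivityLaw":
        return cls(alpha=groups.alpha, beta=groups.beta,
                   mass_fraction_scale=M_C1 * groups.C_C1_s,
                   eta_2=groups.eta_2, mode=mode)

    @classmethod
    def default(cls) -> "ConductivityLaw":
        alpha, beta = conductivity_constants()
        return cls(alpha=alpha, beta=beta,
                   mass_fraction_scale=300.0 * 3.50e-4, eta_2=0.2554)


def _total_collagen(C_C1, C_VCC1, law: ConductivityLaw):
    if law.mode == "linearised":
        return np.asarray(C_C1, dtype=float)
    return np.asarray(C_C1, dtype=float) + law.eta_2 * np.asarray(C_VCC1, dtype=float)


def specific_conductivity(C_C1, C_VCC1, law: ConductivityLaw):
    """Specific hydraulic conductivity kappa in cm^2.

    Arguments are nondimensional concentrations (scale C_C1_s for collagen).
    Raises :class:`SingularConductivityError` when the total collagen is not
    strictly positive (the collagen-starved regime where the power law
    diverges).
    """
    tot = _total_collagen(C_C1, C_VCC1, law)
    if np.any(tot <= 0.0):
        raise SingularConductivityError("total collagen must be strictly positive")
    return law.beta * (law.mass_fraction_scale * tot) ** law.alpha


def dimensionless_mobility(C_C1, C_VCC1, law: ConductivityLaw):
    """kappa~ such that u~ = -kappa~ grad P~ (eta_1 = 1 scaling)."""
    tot = _total_collagen(C_C1, C_VCC1, law)
    if np.any(tot <= 0.0):
        raise SingularConductivityError("total collagen must be strictly positive")
    return tot ** law.alpha


# ---------------------------------------------------------------------------
# P1 assembly helpers
# ---------------------------------------------------------------------------


def p1_gradients(points: np.ndarray, tris: np.ndarray):
    """Per-element P1 shape-function gradients and areas.

    Returns (grads, areas): grads has shape (ntri, 3, 2) with the constant
    gradient of each nodal basis function on each triangle.
    """
    p0 = points[tris[:, 0]]
    p1 = points[tris[:, 1]]
    p2 = points[tris[:, 2]]
    v1 = p1 - p0
    v2 = p2 - p0
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    area = 0.5 * det
    g = np.empty((len(tris), 3, 2))
    # grad N_i = rot90(opposite edge) / (2A)
    g[:, 0, 0] = (p1[:, 1] - p2[:, 1]) / det
    g[:, 0, 1] = (p2[:, 0] - p1[:, 0]) / det
    g[:, 1, 0] = (p2[:, 1] - p0[:, 1]) / det
    g[:, 1, 1] = (p0[:, 0] - p2[:, 0]) / det
    g[:, 2, 0] = (p0[:, 1] - p1[:, 1]) / det
    g[:, 2, 1] = (p1[:, 0] - p0[:, 0]) / det
    return g, area


def stiffness_matrix(points: np.ndarray, tris: np.ndarray,
                     coeff: np.ndarray, n: Optional[int] = None) -> sp.csr_matrix:
    """Assemble sum_e coeff_e * int grad(phi_i).grad(phi_j) over the triangles."""
    if n is None:
        n = len(points)
    g, area = p1_gradients(points, tris)
    ke = np.einsum("eik,ejk->eij", g, g) * (coeff * area)[:, None, None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(points: np.ndarray, tris: np.ndarray,
                n: Optional[int] = None, coeff: Optional[np.ndarray] = None) -> np.ndarray:
    """Row-sum lumped P1 mass (one third of each element area per vertex)."""
    if n is None:
        n = len(points)
    _, area = p1_gradients(points, tris)
    w = area / 3.0 if coeff is None else coeff * area / 3.0
    m = np.zeros(n)
    for k in range(3):
        np.add.at(m, tris[:, k], w)
    return m


def boundary_lumped_length(edges: np.ndarray, points: np.ndarray, n: int) -> np.ndarray:
    """Half of each tagged boundary edge length accumulated at its vertices."""
    out = np.zeros(n)
    if len(edges) == 0:
        return out
    d = points[edges[:, 0]] - points[edges[:, 1]]
    half = 0.5 * np.hypot(d[:, 0], d[:, 1])
    np.add.at(out, edges[:, 0], half)
    np.add.at(out, edges[:, 1], half)
    return out


# ---------------------------------------------------------------------------
# Darcy solver
# ---------------------------------------------------------------------------


@dataclass
class FlowField:
    """Pressure and elementwise velocity on the interstitial subdomain.

    ``P`` is nodal pressure in units of the DA pressure (NaN at nodes
    interior to the LEC where no flow is defined); ``u_elem`` is the
    elementwise-constant dimensionless velocity (zero on LEC triangles).
    ``vessel_fluxes`` holds the consistent (discretely exact) volumetric
    outflux of fluid from each vessel into the interstitium.
    """

    mesh: Mesh
    P: np.ndarray
    u_elem: np.ndarray
    eta_3: float
    vessel_fluxes: Dict[str, float]
    divergence_residual: float

    @property
    def P_s(self) -> np.ndarray:
        """The 'simulated pressure' P~/eta_3 used by the reference runs."""
        return self.P / self.eta_3

    def speed_elem(self) -> np.ndarray:
        return np.hypot(self.u_elem[:, 0], self.u_elem[:, 1])

    def max_speed(self) -> float:
        return float(self.speed_elem().max())

    def mass_balance_error(self) -> float:
        """|net flux| relative to the gross flux through the vessels."""
        net = sum(self.vessel_fluxes.values())
        gross = sum(abs(v) for v in self.vessel_fluxes.values())
        return abs(net) / gross if gross > 0 else 0.0


def solve_darcy(mesh: Mesh,
                kappa_elem: np.ndarray,
                dirichlet: Mapping[str, float | Callable],
                source_nodal: Optional[np.ndarray] = None,
                region: int = 0,
                robin: Optional[Mapping[str, tuple]] = None):
    """Solve div(kappa grad P) + f = 0 on one mesh subdomain (P1, primal).

    ``dirichlet`` maps boundary tags to pressure values (or callables of
    (x, y)).  ``robin`` maps tags to (eta, P_vessel) pairs imposing the
    vascular-permeability condition -n.u = eta*(P_vessel - P) weakly.
    Untagged boundary parts get the natural no-flux condition.
    Returns (P_nodal_full, consistent_flux_per_tag, free_residual_norm).
    """
    pts = mesh.points
    tris = mesh.triangles[mesh.tri_region == region]
    n = len(pts)
    K = stiffness_matrix(pts, tris, kappa_elem, n)
    b = np.zeros(n)
    if source_nodal is not None:
        b += lumped_mass(pts, tris, n) * source_nodal
    robin = dict(robin or {})
    for tag, (eta, p_vessel) in robin.items():
        w = boundary_lumped_length(mesh.boundary_edges[tag], pts, n)
        K = K + sp.diags(eta * w)
        b = b + eta * w * p_vessel

    active = np.unique(tris)
    active_mask = np.zeros(n, dtype=bool)
    active_mask[active] = True

    fixed = np.zeros(n, dtype=bool)
    values = np.zeros(n)
    for tag, val in dirichlet.items():
        nodes = mesh.boundary_nodes(tag)
        nodes = nodes[active_mask[nodes]]
        if len(nodes) == 0:
            raise FlowSolverError(f"no boundary nodes for Dirichlet tag {tag!r}")
        fixed[nodes] = True
        if callable(val):
            values[nodes] = [val(*pts[i]) for i in nodes]
        else:
            values[nodes] = val

    free = active_mask & ~fixed
    idx_free = np.where(free)[0]
    P = np.full(n, np.nan)
    P[fixed] = values[fixed]
    rhs = b[idx_free] - K[idx_free][:, fixed] @ values[fixed]
    A = K[idx_free][:, idx_free]
    try:
        sol = spla.spsolve(A.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise FlowSolverError(f"linear solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise FlowSolverError("linear solve produced non-finite pressures")
    P[idx_free] = sol

    # consistent boundary fluxes: residual of the full system at fixed nodes
    Pz = np.where(np.isnan(P), 0.0, P)
    resid = K @ Pz - b
    fluxes: Dict[str, float] = {}
    for tag in dirichlet:
        nodes = mesh.boundary_nodes(tag)
        nodes = nodes[active_mask[nodes]]
        fluxes[tag] = float(resid[nodes].sum())  # volumetric influx into the domain
    for tag, (eta, p_vessel) in robin.items():
        w = boundary_lumped_length(mesh.boundary_edges[tag], pts, n)
        fluxes[tag] = float((eta * w * (p_vessel - Pz)).sum())
    free_res = float(np.linalg.norm(resid[idx_free]))
    return P, fluxes, free_res


def solve_flow(mesh: Mesh,
               C_C1_nodal: np.ndarray | float,
               groups: DimensionlessGroups,
               vessel_pressures: Optional[Mapping[str, float]] = None,
               law: Optional[ConductivityLaw] = None,
               C_VCC1_nodal: np.ndarray | float = 0.0,
               vessel_bc: str = "dirichlet") -> FlowField:
    """Solve the interstitial (Darcy-limit) flow for a given collagen field.

    ``C_C1_nodal`` is the nondimensional collagen-I field (scalar or nodal
    array); ``vessel_pressures`` are in units of the DA pressure and default
    to the symmetric set {DA: 1, PCV: 0, DLAV: 0}.  ``vessel_bc`` selects
    the leaky-vessel model: ``"dirichlet"`` (default) pins the lumen
    pressures directly, the limit justified by the enormous dimensionless
    permeabilities (eta ~ 1e14); ``"permeable"`` keeps the finite-
    permeability flux conditions -n.u = eta_v (P_v - P).
    """
    if vessel_pressures is None:
        vessel_pressures = DEFAULT_VESSEL_PRESSURES
    if law is None:
        law = ConductivityLaw.from_groups(groups)
    pts = mesh.points
    is_tris = mesh.triangles[mesh.tri_region == 0]

    def elem_mean(field):
        if np.isscalar(field):
            return np.full(len(is_tris), float(field))
        field = np.asarray(field, dtype=float)
        return field[is_tris].mean(axis=1)

    kappa = dimensionless_mobility(elem_mean(C_C1_nodal),
                                   elem_mean(C_VCC1_nodal), law)
    if vessel_bc == "dirichlet":
        dirichlet = {tag: vessel_pressures[tag] for tag in VESSEL_TAGS}
        robin = None
    elif vessel_bc == "permeable":
        etas = {"DA": groups.eta_DA, "PCV": groups.eta_PCV,
                "DLAV": groups.eta_DLAV}
        dirichlet = {}
        robin = {tag: (etas[tag], vessel_pressures[tag])
                 for tag in VESSEL_TAGS}
    else:
        raise FlowSolverError(f"unknown vessel_bc {vessel_bc!r}")
    P, fluxes, free_res = solve_darcy(mesh, kappa, dirichlet, region=0,
                                      robin=robin)

    g, _ = p1_gradients(pts, is_tris)
    Pz = np.where(np.isnan(P), 0.0, P)
    gradP = np.einsum("eik,ei->ek", g, Pz[is_tris])
    u_is = -kappa[:, None] * gradP
    u_elem = np.zeros((mesh.n_triangles, 2))
    u_elem[mesh.tri_region == 0] = u_is

    return FlowField(mesh=mesh, P=P, u_elem=u_elem, eta_3=groups.eta_3,
                     vessel_fluxes=fluxes, divergence_residual=free_res)
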