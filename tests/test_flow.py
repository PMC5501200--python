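"""Interstitial (Darcy-limit) flow solver."""

import numpy as np
import pytest
import sympy

from zflymph import (ConductivityLaw, SingularConductivityError,
                     dimensionless_mobility, solve_darcy, solve_flow,
                     specific_conductivity)
from zflymph.flow import p1_gradients

from conftest import rect_mesh


def l2_error(mesh, P, exact):
    _, area = p1_gradients(mesh.points, mesh.triangles)
    acc = sum((P[mesh.triangles[:, k]] - exact[mesh.triangles[:, k]]) ** 2
              for k in range(3))
    return float(np.sqrt(np.sum(area / 3.0 * acc)))


class TestConductivityLaw:
    def test_beta_at_unit_mass_fraction(self, groups):
        law = ConductivityLaw.from_groups(groups)
        # C~_C1 chosen so the collagen mass fraction is exactly one
        c = 1.0 / law.mass_fraction_scale
        assert specific_conductivity(c, 0.0, law) == pytest.approx(
            6.61e-17, rel=5e-3)

    def test_value_at_reference_collagen(self, groups):
        law = ConductivityLaw.from_groups(groups)
        assert specific_conductivity(1.0, 0.0, law) == pytest.approx(
            2.9e-14, rel=2e-2)

    def test_monotone_decreasing_in_collagen(self, groups):
        law = ConductivityLaw.from_groups(groups)
        c = np.linspace(0.01, 1.0, 50)
        k = specific_conductivity(c, 0.0, law)
        assert np.all(np.diff(k) < 0)

    def test_zero_collagen_is_singular(self, groups):
        law = ConductivityLaw.from_groups(groups)
        with pytest.raises(SingularConductivityError):
            specific_conductivity(0.0, 0.0, law)

    def test_bound_collagen_modes(self, groups):
        law_full = ConductivityLaw.from_groups(groups, mode="full")
        law_lin = ConductivityLaw.from_groups(groups, mode="linearised")
        # bound collagen thickens the matrix in full mode only
        assert (dimensionless_mobility(0.5, 0.1, law_full)
                < dimensionless_mobility(0.5, 0.1, law_lin))


class TestTrunkFlow:
    def test_equal_pressures_no_flow(self, coarse_mesh, groups):
        ff = solve_flow(coarse_mesh, 1.0, groups,
                        vessel_pressures={"DA": 0.3, "PCV": 0.3, "DLAV": 0.3})
        assert ff.max_speed() < 1e-9
        P = ff.P[np.isfinite(ff.P)]
        assert np.allclose(P, 0.3, atol=1e-10)

    def test_global_mass_balance(self, coarse_mesh, groups):
        ff = solve_flow(coarse_mesh, 1.0, groups)
        assert ff.mass_balance_error() < 0.005
        assert ff.vessel_fluxes["DA"] > 0          # DA is the source
        assert ff.vessel_fluxes["PCV"] < 0
        assert ff.vessel_fluxes["DLAV"] < 0

    def test_divergence_residual(self, coarse_mesh, groups):
        ff = solve_flow(coarse_mesh, 1.0, groups)
        scale = abs(ff.vessel_fluxes["DA"])
        assert ff.divergence_residual < 1e-9 * max(scale, 1.0)

    def test_pressure_bounded_by_vessel_values(self, coarse_mesh, groups):
        ff = solve_flow(coarse_mesh, 1.0, groups)
        P = ff.P[np.isfinite(ff.P)]
        assert P.min() > -1e-10 and P.max() < 1.0 + 1e-10

    def test_lower_collagen_strengthens_flow(self, coarse_mesh, groups):
        f1 = solve_flow(coarse_mesh, 1.0, groups)
        f2 = solve_flow(coarse_mesh, 0.1, groups)
        # kappa ~ C^alpha with alpha = -2.7: a tenfold collagen drop
        # multiplies the flow by ~500
        assert f2.max_speed() == pytest.approx(
            f1.max_speed() * 10 ** 2.7, rel=1e-6)

    def test_permeable_vessels_reduce_to_dirichlet(self, coarse_mesh, groups):
        """At the measured dimensionless permeabilities (~1e14) the finite-
        permeability vessel condition is indistinguishable from pinning the
        lumen pressures."""
        fd = solve_flow(coarse_mesh, 1.0, groups, vessel_bc="dirichlet")
        fp = solve_flow(coarse_mesh, 1.0, groups, vessel_bc="permeable")
        assert fp.max_speed() == pytest.approx(fd.max_speed(), rel=1e-6)
        # the transvascular pressure drop is ~1e-14 of the scale, so the
        # extracted Robin flux carries float-cancellation noise ~1e-4
        assert fp.vessel_fluxes["DA"] == pytest.approx(
            fd.vessel_fluxes["DA"], rel=1e-3)
        assert fp.mass_balance_error() < 0.005

    def test_weakly_permeable_vessels_throttle_the_flow(self, coarse_mesh,
                                                        groups):
        import dataclasses
        weak = dataclasses.replace(groups, eta_DA=1.0, eta_PCV=1.0,
                                   eta_DLAV=2.0)
        fw = solve_flow(coarse_mesh, 1.0, weak, vessel_bc="permeable")
        fd = solve_flow(coarse_mesh, 1.0, groups, vessel_bc="dirichlet")
        assert fw.vessel_fluxes["DA"] < 0.5 * fd.vessel_fluxes["DA"]

    def test_peak_speed_stabilises_under_refinement(self, groups):
        from zflymph import build_geometry, generate_mesh
        geo = build_geometry(half_domain=True)
        speeds = []
        for res in (2.8, 2.0, 1.4):
            mesh = generate_mesh(geo, resolution=res, seed=0)
            speeds.append(solve_flow(mesh, 1.0, groups).max_speed())
        assert abs(speeds[-1] - speeds[-2]) < 0.05 * speeds[-1]


class TestOracles:
    def test_manufactured_solution_order(self):
        """P1 Darcy converges at second order on a smooth exact solution."""
        x, y = sympy.symbols("x y")
        Pex = sympy.sin(sympy.pi * x) * sympy.sin(sympy.pi * y)
        kap = 1 + x + 2 * y
        fex = -(sympy.diff(kap * sympy.diff(Pex, x), x)
                + sympy.diff(kap * sympy.diff(Pex, y), y))
        fl = sympy.lambdify((x, y), fex, "numpy")
        Pl = sympy.lambdify((x, y), Pex, "numpy")
        kl = sympy.lambdify((x, y), kap, "numpy")
        errs = []
        for n in (8, 16, 32):
            m = rect_mesh(n, n)
            cent = m.points[m.triangles].mean(axis=1)
            P, _, _ = solve_darcy(
                m, kl(cent[:, 0], cent[:, 1]),
                {t: 0.0 for t in ("left", "right", "bottom", "top")},
                source_nodal=fl(m.points[:, 0], m.points[:, 1]))
            errs.append(l2_error(m, P, Pl(m.points[:, 0], m.points[:, 1])))
        order = np.log2(errs[-2] / errs[-1])
        assert order >= 1.9

    def test_darcy_limit_analytic_profile(self):
        """1D variable-conductivity profile: P(x) = 1 - 2(1 - 1/(1+x))."""
        errs, fluxes = [], []
        for n in (8, 16, 32):
            m = rect_mesh(n, max(2, n // 4), 1.0, 0.25)
            cent = m.points[m.triangles].mean(axis=1)
            P, fx, _ = solve_darcy(m, (1 + cent[:, 0]) ** 2,
                                   {"left": 1.0, "right": 0.0})
            exact = 1 - 2 * (1 - 1 / (1 + m.points[:, 0]))
            errs.append(l2_error(m, P, exact))
            fluxes.append(fx["left"])
        order = np.log2(errs[-2] / errs[-1])
        assert order >= 1.9
        # u = -kappa dP/dx = 2 everywhere; width 0.25 -> flux 0.5
        assert fluxes[-1] == pytest.approx(0.5, rel=1e-3)
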