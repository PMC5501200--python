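"""Transport coefficients, reaction network and the coupled integrator."""

import numpy as np
import pytest

from zflymph import (TransportConfig, TransportSystem, boundary_condition_summary,
                     effective_diffusivity, exclusion_fraction,
                     reaction_rates_IS, reaction_rates_LEC)
from zflymph.diagnostics import interpolate_field
from zflymph.transport import TransportError

from conftest import PRIMARY_SPECIES


class TestCoefficients:
    def test_exclusion_no_collagen(self, groups):
        assert exclusion_fraction(0.0, 0.0, groups, "full") == 1.0

    def test_exclusion_at_reference_collagen(self, groups):
        om = exclusion_fraction(1.0, 0.0, groups, "full")
        assert om == pytest.approx(1.0 - groups.lam["5"], rel=1e-12)
        assert om == pytest.approx(0.802, rel=5e-3)

    def test_exclusion_truncation_error_bound(self, groups):
        # |1/omega_full - (1 + lam5 C)| < 0.05 over the physical range
        c = np.linspace(0.0, 1.0, 201)
        full = 1.0 / exclusion_fraction(c, 0.0, groups, "full")
        simp = 1.0 + groups.lam["5"] * c
        assert np.max(np.abs(full - simp)) < 0.05

    def test_exclusion_invalid_state(self, groups):
        with pytest.raises(TransportError):
            exclusion_fraction(6.0, 0.0, groups, "full")

    def test_diffusivity_free_fluid_limit(self, groups):
        for s in ("VC", "M2", "T2"):
            for mode in ("full", "simplified", "free"):
                assert effective_diffusivity(s, 0.0, 0.0, groups, mode) \
                    == pytest.approx(groups.lam_1[s])

    def test_diffusivity_simplified_value(self, groups):
        d = effective_diffusivity("VC", 1.0, 0.0, groups, "simplified")
        expect = groups.lam_1["VC"] * (1 - groups.lam_2["VC"]
                                       * np.sqrt(groups.lam["3"]))
        assert d == pytest.approx(expect, rel=1e-12)
        assert d == pytest.approx(5.66, rel=2e-2)

    def test_ogston_truncation_error_measured(self, groups):
        """The first-order Taylor form tracks the exponential to ~18% for
        VEGFC (the largest hindrance ratio) and ~4% for TIMP2 at full
        collagen; agreement tightens to 2% only below C~_C1 ~ 0.02."""
        c = np.linspace(0.0, 1.0, 201)
        for s, bound in (("VC", 0.19), ("T2", 0.04)):
            full = effective_diffusivity(s, c, 0.0, groups, "full")
            simp = effective_diffusivity(s, c, 0.0, groups, "simplified")
            dev = np.max(np.abs(full - simp) / full)
            assert dev < bound
        c_small = np.linspace(0.0, 0.015, 101)
        full = effective_diffusivity("VC", c_small, 0.0, groups, "full")
        simp = effective_diffusivity("VC", c_small, 0.0, groups, "simplified")
        assert np.max(np.abs(full - simp) / full) < 0.02


class TestReactionNetwork:
    LEC_ZERO = {k: 0.0 for k in ("M2P", "M2", "T2", "MT1", "MT1T2",
                                 "MT1T2M2P")}
    IS_ZERO = {k: 0.0 for k in ("VC", "M2", "M2P", "T2", "M2T2", "C1",
                                "VCC1")}

    def test_lec_constant_production_terms(self, groups):
        r = reaction_rates_LEC(self.LEC_ZERO, groups)
        assert float(r["M2P"][0]) == 1.0
        assert float(r["T2"][0]) == 1.0
        for s in ("M2", "MT1", "MT1T2", "MT1T2M2P"):
            assert float(r[s][0]) == 0.0

    def test_is_rates_vanish_at_zero(self, groups):
        r = reaction_rates_IS(self.IS_ZERO, groups)
        for v in r.values():
            assert float(np.abs(v).max()) == 0.0

    def test_mt1_pool_conserved_pointwise(self, groups):
        rng = np.random.default_rng(7)
        state = {k: rng.random(100) for k in self.LEC_ZERO}
        r = reaction_rates_LEC(state, groups)
        total = r["MT1"] + r["MT1T2"] + r["MT1T2M2P"]
        assert np.abs(total).max() < 1e-8       # float rounding of ~1e6 terms

    def test_activation_group_is_unity(self, groups):
        state = dict(self.LEC_ZERO, MT1=1.0, MT1T2M2P=1.0)
        r = reaction_rates_LEC(state, groups)
        assert float(r["M2"][0]) == pytest.approx(1.0)

    def test_collagenolysis_michaelis_menten(self, groups):
        state = dict(self.IS_ZERO, M2=1.0, C1=1.0)
        r = reaction_rates_IS(state, groups)
        expect = -groups.lam["28"] / (groups.K_M + groups.C_C1_s)
        assert float(r["C1"][0]) == pytest.approx(expect, rel=1e-12)
        assert float(r["C1"][0]) == pytest.approx(-21.4, rel=1e-2)

    def test_binding_group_is_unity(self, groups):
        state = dict(self.IS_ZERO, VC=1.0, C1=1.0)
        r = reaction_rates_IS(state, groups)
        assert float(r["VCC1"][0]) == pytest.approx(1.0)

    def test_binding_multiplier_scales_forward_terms_only(self, groups):
        state = dict(self.IS_ZERO, VC=0.5, C1=0.5, VCC1=0.2)
        r1 = reaction_rates_IS(state, groups, binding_multiplier=1.0)
        r10 = reaction_rates_IS(state, groups, binding_multiplier=10.0)
        fwd = 10.0 * 0.25 - groups.lam["32"] * 0.2
        assert float(r10["VCC1"][0]) == pytest.approx(fwd)
        drop = float(r1["VC"][0] - r10["VC"][0])
        assert drop == pytest.approx(9.0 * groups.lam["25"] * 0.25)

    def test_constant_m2_override(self, groups):
        r = reaction_rates_LEC({"M2": 0.0}, groups,
                               constant_m2_production=10.0)
        assert float(r["M2"][0]) == 10.0


class TestSystem:
    def test_boundary_condition_summary(self):
        cfg = TransportConfig(species=PRIMARY_SPECIES)
        bc = boundary_condition_summary(cfg)
        assert bc["VC"]["DA"].startswith("constant influx")
        assert bc["M2"]["DA"] == "no-flux"
        assert bc["M2P"]["LEC"] == "flux and concentration continuity"
        assert bc["VC"]["LEC"] == "no-flux"
        assert "C1" not in bc                   # immobile species carry no BCs

    def test_closed_system_conserves_vegfc(self, coarse_mesh, groups):
        """No influx, no reactions: total VEGFC moles stay constant."""
        cfg = TransportConfig(species=("VC",), C1_constant=1.0,
                              influx_scale=0.0)
        system = TransportSystem(coarse_mesh, groups, cfg)
        system.reactions = []
        y0 = system.initial_state()
        rng = np.random.default_rng(3)
        y0[:] = rng.random(system.n_dof)
        traj = system.advance(t_end=0.05, checkpoints=(0.025, 0.05), y0=y0)
        def total(state):
            vc = system.global_field("VC", state.fields["VC"])
            return float((system.mass_is * vc).sum())
        t0 = total(traj.states[0])
        for st in traj.states[1:]:
            assert total(st) == pytest.approx(t0, rel=1e-8)

    def test_influx_flux_balance(self, coarse_mesh, groups):
        """With the DA source on and all sinks off, d/dt of total VEGFC
        equals the nondimensional DA arc length."""
        cfg = TransportConfig(species=("VC",), C1_constant=1.0)
        system = TransportSystem(coarse_mesh, groups, cfg)
        system.reactions = []
        traj = system.advance(t_end=0.1, checkpoints=(0.05, 0.1))
        arc = system.da_weights.sum()
        for st in traj.states:
            vc = system.global_field("VC", st.fields["VC"])
            assert (system.mass_is * vc).sum() == pytest.approx(
                arc * st.t, rel=1e-7, abs=1e-14)

    def test_pure_diffusion_matches_radial_reference(self, groups):
        """Short-time VEGFC spread from the DA against an independent 1D
        radial Crank-Nicolson reference (valid while the front is far from
        walls and the LEC)."""
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        from zflymph import build_geometry, generate_mesh
        geo = build_geometry(half_domain=True)
        mesh = generate_mesh(geo, seed=0, h_circle=0.002, h_max=0.008)
        cfg = TransportConfig(species=("VC",), C1_constant=1.0,
                              flow_enabled=False, diffusivity_mode="free")
        system = TransportSystem(mesh, groups, cfg)
        system.reactions = []
        T = 2.5e-5
        traj = system.advance(t_end=T, checkpoints=(T,))
        vc = system.global_field("VC", traj.state_at(T).fields["VC"])

        D = groups.lam_1["VC"]
        da = geo.circles["DA"]
        n = 3000
        r = np.linspace(da.r, da.r + 0.05, n)
        dr = r[1] - r[0]
        rf = 0.5 * (r[:-1] + r[1:])
        main = np.zeros(n); lo = np.zeros(n - 1); up = np.zeros(n - 1)
        for i in range(1, n - 1):
            a = D * rf[i - 1] / (r[i] * dr * dr)
            b = D * rf[i] / (r[i] * dr * dr)
            lo[i - 1] = a; up[i] = b; main[i] = -(a + b)
        main[0] = -D * rf[0] / (r[0] * dr * dr)
        up[0] = D * rf[0] / (r[0] * dr * dr)
        L = sp.diags([lo, main, up], [-1, 0, 1]).tocsc()
        bvec = np.zeros(n); bvec[0] = da.r / (r[0] * dr)
        I = sp.eye(n).tocsc()
        dt = 2e-8
        lu = spla.splu((I - dt / 2 * L).tocsc())
        B = I + dt / 2 * L
        C = np.zeros(n)
        for _ in range(int(T / dt)):
            C = lu.solve(B @ C + dt * bvec)
        rho = np.linspace(da.r + 0.001, da.r + 0.02, 25)
        pts = np.column_stack([np.full(25, -1e-9), da.cy - rho])
        vals = interpolate_field(mesh, np.nan_to_num(vc), pts)
        ref = np.interp(rho, r, C)
        assert np.nanmax(np.abs(vals - ref)) < 0.02 * ref.max()

    def test_peclet_ordering(self, groups):
        """VEGFC has the smallest diffusion group, hence the largest local
        convection-dominance measure of all mobile species."""
        pe = {s: groups.lam["7"] / groups.lam_1[s] for s in groups.lam_1}
        assert max(pe, key=pe.get) == "VC"

    def test_tenfold_influx_linearity(self, coarse_mesh, groups):
        """With sequestration on but collagen feedback negligible, scaling
        the DA release tenfold scales VEGFC (and its bound pool) tenfold."""
        fields = {}
        for scale in (1.0, 10.0):
            cfg = TransportConfig(species=("VC", "C1", "VCC1"),
                                  C1_initial=1.0, influx_scale=scale)
            system = TransportSystem(coarse_mesh, groups, cfg)
            traj = system.advance(t_end=0.2, checkpoints=(0.2,))
            fields[scale] = traj.state_at(0.2).fields
        for s in ("VC", "VCC1"):
            a, b = fields[1.0][s], fields[10.0][s]
            big = np.abs(a) > 1e-6 * np.abs(a).max()
            ratio = b[big] / (10.0 * a[big])
            assert np.max(np.abs(ratio - 1.0)) < 0.01

    def test_primary_nonnegative_at_checkpoints(self, primary_coarse):
        for st in primary_coarse.states:
            for name, v in st.clipped().items():
                assert v.min() >= 0.0, name

    def test_primary_mt1_conservation(self, primary_coarse):
        for st in primary_coarse.states:
            total = (st.fields["MT1"] + st.fields["MT1T2"]
                     + st.fields["MT1T2M2P"])
            assert np.abs(total - 1.0).max() < 1e-6

    def test_primary_matches_well_mixed_oracle(self, primary_coarse):
        """Spatial means of the slow species agree with an independent
        two-compartment well-mixed ODE reduction (diffusion is fast, so the
        fields are near-uniform and the reduction is accurate to ~2%)."""
        from scipy.integrate import solve_ivp
        system = primary_coarse.system
        g = system.groups
        lam = g.lam
        A_L = system.area_lec.sum()
        A = system.area_is.sum() + A_L
        f_L = A_L / A
        f_IS = 1 - f_L

        def rhs(t, y):
            M2P, M2, T2, M2T2, MT1, MT1T2, TERN, C1 = y
            return [
                f_L * (1 - lam["9"] * MT1T2 * M2P + lam["10"] * TERN)
                - f_IS * lam["11"] * M2P,
                f_L * TERN * MT1 + f_IS * (-lam["13"] * M2 * T2
                                           + lam["14"] * M2T2
                                           - lam["15"] * M2),
                f_L * (1 - lam["17"] * MT1 * T2 + lam["18"] * MT1T2)
                + f_IS * (-lam["19"] * M2 * T2 + lam["20"] * M2T2
                          - lam["21"] * T2),
                f_IS * (M2 * T2 - lam["23"] * M2T2 - lam["24"] * M2T2),
                -lam["33"] * MT1 * T2 + lam["34"] * MT1T2,
                lam["35"] * MT1 * T2 - lam["36"] * MT1T2
                - lam["37"] * MT1T2 * M2P + lam["38"] * TERN
                + lam["39"] * TERN * MT1,
                lam["40"] * MT1T2 * M2P - lam["41"] * TERN
                - lam["42"] * TERN * MT1,
                -lam["28"] * M2 * C1 / (g.K_M + g.C_C1_s * C1),
            ]

        sol = solve_ivp(rhs, (0, 1), [0, 0, 0, 0, 1, 0, 0, 1],
                        method="LSODA", rtol=1e-10, atol=1e-18)
        ref = dict(zip(["M2P", "M2", "T2", "M2T2", "MT1", "MT1T2",
                        "MT1T2M2P", "C1"], sol.y[:, -1]))
        st = primary_coarse.state_at(1.0)
        for s in ("M2P", "M2", "T2"):
            assert np.mean(st.fields[s]) == pytest.approx(ref[s], rel=0.02)
        # the MT1 pool depletes fast and is most sensitive to the local
        # (vs well-mixed) TIMP2 seen by the LEC; the reduction is ~10% there
        for s in ("MT1", "MT1T2", "MT1T2M2P"):
            assert np.mean(st.fields[s]) == pytest.approx(ref[s], rel=0.10)
        assert st.fields["C1"].min() == pytest.approx(ref["C1"], abs=5e-5)

    def test_max_step_halving_insensitivity(self, coarse_mesh, groups):
        """Halving the maximum step leaves the final minimum collagen
        unchanged to well within the documented 1e-5 relative band."""
        mins = {}
        for ms in (0.02, 0.01):
            cfg = TransportConfig(species=PRIMARY_SPECIES, C1_initial=1.0,
                                  max_step=ms)
            system = TransportSystem(coarse_mesh, groups, cfg)
            traj = system.advance(t_end=1.0, checkpoints=(1.0,))
            mins[ms] = traj.state_at(1.0).fields["C1"].min()
        assert abs(mins[0.02] - mins[0.01]) / mins[0.02] < 1e-5
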