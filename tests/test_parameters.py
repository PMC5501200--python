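"""Characteristic scales, dimensionless groups and parameter derivations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zflymph import (InvalidParameterError, ParameterSet, average_da_pressure,
                     compute_groups, compute_scales, initial_time_step,
                     molecules_per_cell_to_molar, stokes_einstein_radius)
from zflymph.parameters import MMHG_TO_CMH2O, MMHG_TO_PA


def rel(a, b):
    return abs(a - b) / abs(b)


# published values for the concentration scales (molar)
SCALE_TABLE = {
    "C1": 3.50e-4, "VC": 1.64e-10, "VCC1": 8.93e-5, "M2": 3.94e-5,
    "M2P": 1.14e-3, "M2T2": 6.68e1, "MT1": 5.71e-7, "MT1T2": 5.71e-7,
    "MT1T2M2P": 5.71e-7, "T2": 6.65e-6,
}

# published values for the flow/transport groups
GROUP_TABLE = {
    "eta_2": 0.255, "eta_3": 1.542e-11, "eta_DA": 1.317e14,
    "eta_PCV": 1.317e14, "eta_DLAV": 2.634e14,
}

LAM1_TABLE = {"VC": 1.15e1, "M2": 1.95e1, "M2P": 1.83e1, "M2T2": 1.72e1,
              "T2": 2.52e1}
LAM2_TABLE = {"VC": 1.81, "M2": 1.07, "M2P": 1.14, "M2T2": 1.21,
              "T2": 8.26e-1}
LAM_TABLE = {
    "3": 7.88e-2, "4": 2.01e-2, "5": 1.98e-1, "6": 5.06e-2, "7": 1.36e-2,
    "8": 1.0, "9": 3.45e3, "10": 1.02e-1, "11": 4.32, "12": 1.0,
    "13": 1.69e6, "14": 4.61e11, "15": 4.32, "16": 1.0, "17": 8.73e4,
    "18": 7.42e-1, "19": 1.0e7, "20": 2.73e12, "21": 4.32, "22": 1.0,
    "23": 2.72e5, "24": 4.32, "25": 5.44e5, "26": 8.47e7, "27": 4.32,
    "DA_VC": 1.0, "28": 7.66e-3, "29": 2.55e-1, "30": 3.97e1, "31": 1.0,
    "32": 1.56e2, "33": 1.02e6, "34": 8.64, "35": 1.02e6, "36": 8.64,
    "37": 6.89e6, "38": 2.03e2, "39": 6.91e1, "40": 6.89e6, "41": 2.03e2,
    "42": 6.91e1,
}


class TestScales:
    def test_velocity_scale(self, scales):
        assert rel(scales.U, 1.371e-4) < 5e-3

    @pytest.mark.parametrize("species,value", sorted(SCALE_TABLE.items()))
    def test_concentration_scales(self, scales, species, value):
        assert rel(scales.C_s[species], value) < 5e-3

    def test_fixed_scales(self, scales, params):
        assert scales.L == 434.0
        assert scales.tau == 43200.0
        assert scales.P_scale == params.P_DA

    def test_mt1_pool_shares_one_scale(self, scales, params):
        for s in ("MT1", "MT1T2", "MT1T2M2P"):
            assert scales.C_s[s] == params.C_MT1_0
        assert scales.C_s["C1"] == params.C_C1_0


class TestGroups:
    def test_eta1_unity_by_construction(self, groups):
        assert abs(groups.eta_1 - 1.0) < 1e-12

    @pytest.mark.parametrize("name,value", sorted(GROUP_TABLE.items()))
    def test_flow_groups(self, groups, name, value):
        assert rel(getattr(groups, name), value) < 5e-3

    @pytest.mark.parametrize("species,value", sorted(LAM1_TABLE.items()))
    def test_diffusion_numbers(self, groups, species, value):
        assert rel(groups.lam_1[species], value) < 5e-3

    @pytest.mark.parametrize("species,value", sorted(LAM2_TABLE.items()))
    def test_hindrance_ratios(self, groups, species, value):
        assert rel(groups.lam_2[species], value) < 5e-3

    @pytest.mark.parametrize("key,value", sorted(LAM_TABLE.items()))
    def test_kinetic_groups(self, groups, key, value):
        # lambda_19 is published to one significant figure (1e7)
        tol = 5e-2 if key == "19" else 5e-3
        assert rel(groups.lam[key], value) < tol

    def test_unity_groups_exact(self, groups):
        for key in ("8", "12", "16", "22", "31", "DA_VC"):
            assert abs(groups.lam[key] - 1.0) < 1e-12

    def test_degradation_groups_all_equal(self, groups):
        vals = [groups.lam[k] for k in ("11", "15", "21", "24", "27")]
        assert np.allclose(vals, vals[0], rtol=1e-14)
        assert abs(vals[0] - 4.32) < 1e-12

    def test_mt1_scale_degeneracies(self, groups):
        # one shared scale for the MT1 pool collapses these group pairs
        for a, b in (("35", "33"), ("36", "34"), ("40", "37"),
                     ("41", "38"), ("42", "39")):
            assert rel(groups.lam[a], groups.lam[b]) < 1e-13

    def test_beta_from_regression_intercept(self, groups):
        assert rel(groups.beta, 6.61e-17) < 5e-3


class TestDerivations:
    def test_da_pressure_average(self):
        assert average_da_pressure(0.2433, 0.1255) == pytest.approx(0.1844)

    def test_da_pressure_identity_and_arith(self):
        assert average_da_pressure(0.7, 0.7) == 0.7
        assert average_da_pressure(0.2, 0.1) == pytest.approx(0.15)

    def test_da_pressure_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            average_da_pressure(-0.1, 0.2)
        with pytest.raises(InvalidParameterError):
            average_da_pressure(0.1, 0.0)

    def test_molecules_per_cell(self):
        assert rel(molecules_per_cell_to_molar(180000, 10.0), 5.71e-7) < 5e-3
        assert molecules_per_cell_to_molar(0, 10.0) == 0.0
        half = molecules_per_cell_to_molar(90000, 10.0)
        full = molecules_per_cell_to_molar(180000, 10.0)
        assert half == pytest.approx(full / 2)

    def test_stokes_einstein(self):
        r = stokes_einstein_radius(1.10e-6, 1.2, 298.0)
        assert rel(r, 1.65e-9) < 2e-2       # ~1.65 nm for TIMP2
        assert stokes_einstein_radius(2.2e-6, 1.2, 298.0) == pytest.approx(r / 2)
        assert stokes_einstein_radius(1.1e-6, 1.2, 0.0) == 0.0
        with pytest.raises(InvalidParameterError):
            stokes_einstein_radius(0.0, 1.2, 298.0)

    def test_initial_time_step(self, params):
        # diffusive time over 1 um for the fastest species, nondimensional
        assert rel(initial_time_step(params), 2.10e-7) < 5e-3

    def test_unit_conversion_round_trip(self):
        p = 0.1844
        assert p * MMHG_TO_PA / MMHG_TO_PA == pytest.approx(p, rel=1e-12)
        assert p * MMHG_TO_CMH2O / MMHG_TO_CMH2O == pytest.approx(p, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ParameterSet(mu=-1.0)
        with pytest.raises(InvalidParameterError):
            ParameterSet(C_C1_0=0.0)

    def test_yaml_round_trip(self, tmp_path, params):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        back = ParameterSet.from_yaml(path)
        assert back == params


@settings(max_examples=25, deadline=None)
@given(p_m2p=st.floats(1e-10, 1e-6), p_t2=st.floats(1e-12, 1e-8),
       r_da=st.floats(1e-19, 1e-15), k_act=st.floats(1e1, 1e5))
def test_scale_construction_invariants(p_m2p, p_t2, r_da, k_act):
    """The production/binding groups pinned to one stay one for any inputs."""
    p = ParameterSet(P_M2P=p_m2p, P_T2=p_t2, R_DA_VC=r_da, k_eff_act=k_act)
    g = compute_groups(p, compute_scales(p))
    for key in ("8", "12", "16", "22", "31", "DA_VC"):
        assert abs(g.lam[key] - 1.0) < 1e-10
    assert abs(g.eta_1 - 1.0) < 1e-10
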