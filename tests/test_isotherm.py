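"""Langmuir isotherm law, fitting, batch equilibrium and dye conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellsorb as cs
from cellsorb.errors import FitError, InvalidInputError

SGCS_P = cs.LangmuirParams(q_m=2.83, K_a=6.22)
UGCS_P = cs.LangmuirParams(q_m=5.61, K_a=11.5)

log_param = st.floats(np.log10(0.1), np.log10(100.0))


class TestLangmuirLaw:
    def test_zero_concentration(self):
        assert cs.langmuir_bound(0.0, SGCS_P) == 0.0

    def test_half_saturation(self):
        assert cs.langmuir_bound(1.0 / SGCS_P.K_a, SGCS_P) == pytest.approx(
            SGCS_P.q_m / 2.0, rel=1e-12)

    def test_equilibrium_point_value(self):
        assert cs.langmuir_bound(0.1100, SGCS_P) == pytest.approx(1.1496, abs=2e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.langmuir_bound(-0.1, SGCS_P)

    @settings(max_examples=40, deadline=None)
    @given(lq=log_param, lk=log_param, c=st.floats(1e-6, 10.0))
    def test_monotone_concave_and_bounded(self, lq, lk, c):
        p = cs.LangmuirParams(10 ** lq, 10 ** lk)
        q1, q2 = cs.langmuir_bound(np.array([c, 2 * c]), p)
        assert 0 < q1 < q2 < p.q_m  # increasing, below capacity
        # concavity: chord midpoint below the curve
        mid = cs.langmuir_bound(1.5 * c, p)
        assert mid >= (q1 + q2) / 2 - 1e-12

    @settings(max_examples=40, deadline=None)
    @given(lq=log_param, lk=log_param, c=st.floats(0.0, 5.0))
    def test_slope_matches_numerical_derivative(self, lq, lk, c):
        p = cs.LangmuirParams(10 ** lq, 10 ** lk)
        h = 1e-8
        num = (cs.langmuir_bound(c + h, p) - cs.langmuir_bound(max(c - h, 0.0), p)) / (
            (c + h) - max(c - h, 0.0))
        assert cs.langmuir_slope(c, p) == pytest.approx(num, rel=1e-5)

    def test_slope_limits(self):
        assert cs.langmuir_slope(0.0, SGCS_P) == pytest.approx(17.60, abs=5e-3)
        assert cs.langmuir_slope(1e9, SGCS_P) < 1e-15
        assert cs.langmuir_slope(0.079436, UGCS_P) == pytest.approx(17.62, abs=5e-3)


class TestBondingStrength:
    @pytest.mark.parametrize("p, expected", [
        (SGCS_P, 17.60), (UGCS_P, 64.52), (cs.LangmuirParams(1.0, 1.0), 1.0),
    ])
    def test_values(self, p, expected):
        assert cs.bonding_strength(p) == pytest.approx(expected, abs=5.1e-3)


class TestFitLangmuir:
    def test_noiseless_self_consistency(self):
        C = np.array([0.01, 0.03, 0.06, 0.1, 0.2, 0.4])
        q = cs.langmuir_bound(C, UGCS_P)
        rep = cs.fit_langmuir((C, q))
        assert rep.params.q_m == pytest.approx(UGCS_P.q_m, rel=1e-6)
        assert rep.params.K_a == pytest.approx(UGCS_P.K_a, rel=1e-6)
        assert rep.R2 > 1 - 1e-12 and rep.RMSE < 1e-8

    @settings(max_examples=25, deadline=None)
    @given(lq=log_param, lk=log_param)
    def test_noiseless_recovery_across_parameter_space(self, lq, lk):
        p = cs.LangmuirParams(10 ** lq, 10 ** lk)
        C = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0]) / p.K_a
        rep = cs.fit_langmuir((C, cs.langmuir_bound(C, p)))
        assert rep.params.q_m == pytest.approx(p.q_m, rel=1e-6)
        assert rep.params.K_a == pytest.approx(p.K_a, rel=1e-6)

    def test_noisy_recovery(self, ugcs):
        df = cs.gen_equilibrium(ugcs.system, UGCS_P, reps=2,
                                noise=cs.NoiseModel(sd_rel=0.03, seed=0))
        rep = cs.fit_langmuir(df)
        assert rep.params.q_m == pytest.approx(UGCS_P.q_m, rel=0.15)
        assert rep.params.K_a == pytest.approx(UGCS_P.K_a, rel=0.15)

    def test_linear_regime_flagged_ill_conditioned(self):
        # far below 1/K_a the model is q ~ (q_m K_a) C: only the product is known
        C = np.linspace(1e-6, 1e-4, 8)
        rep = cs.fit_langmuir((C, 17.6 * C))
        assert rep.condition_number > 1e4
        assert any("ill-conditioned" in w for w in rep.warnings)

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError):
            cs.fit_langmuir((np.full(5, 0.1), np.full(5, 1.0)))


class TestBatchEquilibrium:
    def test_reference_fixed_points(self, sgcs, ugcs):
        C_f, q = cs.batch_equilibrium(sgcs.system, SGCS_P)
        assert C_f == pytest.approx(0.1100, abs=1e-4)
        assert q == pytest.approx(1.1496, abs=2e-4)
        C_f, q = cs.batch_equilibrium(ugcs.system, UGCS_P)
        assert C_f == pytest.approx(0.07944, abs=1e-4)
        assert q == pytest.approx(2.678, abs=2e-3)

    def test_empty_bath(self, sgcs):
        from dataclasses import replace
        assert cs.batch_equilibrium(replace(sgcs.system, C_0=0.0), SGCS_P) == (0.0, 0.0)

    @settings(max_examples=40, deadline=None)
    @given(lq=log_param, lk=log_param, C_0=st.floats(1e-4, 2.0))
    def test_satisfies_isotherm_and_mass_balance(self, sgcs, lq, lk, C_0):
        from dataclasses import replace
        p = cs.LangmuirParams(10 ** lq, 10 ** lk)
        sys = replace(sgcs.system, C_0=C_0)
        C_f, q = cs.batch_equilibrium(sys, p)
        assert q == pytest.approx(cs.langmuir_bound(C_f, p), rel=1e-10)
        assert C_f == pytest.approx(C_0 - q * sys.m / sys.V_L, rel=1e-10, abs=1e-12)


class TestDyeSurfaceArea:
    def test_congo_red_inversion(self):
        assert cs.dye_surface_area(0.27561, "congo_red") == pytest.approx(290.76, abs=0.05)

    def test_congo_red_direct(self):
        assert cs.dye_surface_area(0.1, "congo_red") == pytest.approx(105.5)

    def test_azure_b_zero(self):
        assert cs.dye_surface_area(0.0, "azure_b") == 0.0

    def test_unknown_dye_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.dye_surface_area(0.1, "methylene_blue")
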