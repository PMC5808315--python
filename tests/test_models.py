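"""Closed-form Sharpe-Schoolfield mathematics and normalisation alternatives.

Expected values marked as oracle-derived were computed once by independent
direct arithmetic (or brute-force search) and frozen here.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tpcfit as t
from tpcfit.models import NoPeakError

from conftest import brute_force_t_pk

K = t.BOLTZMANN_EV


class TestSSRate:
    def test_frozen_oracle_value(self, canonical_params):
        # hand-evaluated formula at T=300 K, T_ref=273.15 K
        p = t.SSParams(B0=1, E=0.65, E_D=3.0, T_h=310, T_ref=273.15)
        assert t.ss_rate(p, 300.0) == pytest.approx(11.567630750485021, rel=1e-12)

    def test_far_below_th_equals_b0_at_tref(self):
        # T_h - T_ref = 100 K: denominator ~ 1, so rate(T_ref) ~ B0
        p = t.SSParams(B0=3.2, E=0.65, E_D=3.0, T_h=380.0, T_ref=280.0)
        assert t.ss_rate(p, 280.0) == pytest.approx(3.2, rel=1e-4)

    def test_at_th_with_zero_rise_is_half_arrhenius(self):
        # E -> 0: numerator is B0 at every T; denominator at T_h is 2
        p = t.SSParams(B0=5.0, E=1e-12, E_D=2.0, T_h=300.0, T_ref=280.0)
        assert t.ss_rate(p, 300.0) == pytest.approx(2.5, rel=1e-9)

    def test_vectorised_and_positive(self, canonical_params):
        out = t.ss_rate(canonical_params, np.array([280.0, 300.0, 320.0]))
        assert out.shape == (3,) and np.all(out > 0)

    @pytest.mark.parametrize("bad_T", [-5.0, 0.0, np.nan, np.inf])
    def test_rejects_nonphysical_temperature(self, canonical_params, bad_T):
        with pytest.raises(ValueError):
            t.ss_rate(canonical_params, bad_T)

    def test_extreme_parameters_underflow_not_overflow(self):
        p = t.SSParams(B0=1.0, E=0.5, E_D=50.0, T_h=200.0, T_ref=280.0)
        val = t.ss_rate(p, 440.0)
        assert np.isfinite(val) and val >= 0.0


class TestActivityFraction:
    def test_half_at_th(self):
        for e_d in (0.5, 2.0, 6.0):
            for t_h in (270.0, 300.0, 330.0):
                assert t.activity_fraction(e_d, t_h, t_h) == pytest.approx(0.5, abs=1e-12)

    def test_fully_active_far_below_th(self):
        assert t.activity_fraction(3.0, 300.0, 150.0) == pytest.approx(1.0, abs=1e-10)

    def test_frozen_oracle_value(self):
        assert t.activity_fraction(2.0, 300.0, 310.0) == pytest.approx(
            0.07616075242828364, rel=1e-12)

    @given(st.floats(0.5, 6.0), st.floats(270.0, 330.0))
    @settings(max_examples=30, deadline=None)
    def test_strictly_decreasing_in_t(self, e_d, t_h):
        # window around T_h keeps the logistic away from float saturation
        grid = np.linspace(t_h - 25.0, t_h + 25.0, 60)
        vals = t.activity_fraction(e_d, t_h, grid)
        assert np.all(np.diff(vals) < 0)


class TestBAtTref:
    def test_half_b0_at_th(self):
        p = t.SSParams(B0=4.0, E=0.6, E_D=2.0, T_h=290.0, T_ref=290.0)
        assert t.b_at_tref(p) == pytest.approx(2.0, rel=1e-12)

    def test_frozen_oracle_value(self):
        p = t.SSParams(B0=2.0, E=0.6, E_D=2.0, T_h=290.0, T_ref=280.0)
        assert t.b_at_tref(p) == pytest.approx(1.8914990730646228, rel=1e-12)

    def test_identical_to_ss_rate_at_tref(self, canonical_params):
        assert t.b_at_tref(canonical_params) == pytest.approx(
            float(t.ss_rate(canonical_params, canonical_params.T_ref)), rel=1e-12)

    @given(st.floats(0.3, 2.0), st.floats(1.0, 6.0), st.floats(270.0, 330.0),
           st.floats(260.0, 320.0))
    @settings(max_examples=40, deadline=None)
    def test_always_strictly_below_b0(self, e, e_d, t_h, t_ref):
        p = t.SSParams(B0=1.0, E=e, E_D=e_d, T_h=t_h, T_ref=t_ref)
        # mathematically strict; equality only once the denominator's
        # exponential falls below float resolution
        if t.inflation_fold(p) > 1.0 + 1e-14:
            assert t.b_at_tref(p) < p.B0
        else:
            assert t.b_at_tref(p) <= p.B0
        assert t.inflation_fold(p) >= 1.0


class TestTpkPpk:
    def test_tpk_equals_th_when_ed_is_2e(self):
        p = t.SSParams(B0=1.0, E=0.7, E_D=1.4, T_h=305.0, T_ref=280.0)
        assert t.t_pk(p) == pytest.approx(305.0, abs=1e-9)
        assert t.p_pk(p) == pytest.approx(float(t.ss_rate(p, 305.0)), rel=1e-12)

    def test_frozen_brute_force_values(self):
        p1 = t.SSParams(B0=1.0, E=0.65, E_D=3.0, T_h=310.0, T_ref=273.15)
        assert t.t_pk(p1) == pytest.approx(306.49258921017764, abs=1e-5)
        # E < E_D < 2E: the peak sits above T_h
        p2 = t.SSParams(B0=1.0, E=0.6, E_D=0.9, T_h=300.0, T_ref=280.0)
        assert t.t_pk(p2) == pytest.approx(306.0941813432013, abs=1e-5)
        assert t.t_pk(p2) > p2.T_h

    def test_no_peak_is_an_explicit_error(self):
        p = t.SSParams(B0=1.0, E=1.0, E_D=0.9, T_h=300.0, T_ref=280.0)
        with pytest.raises(NoPeakError):
            t.t_pk(p)
        with pytest.raises(NoPeakError):
            t.p_pk(p)

    def test_closed_form_matches_numeric_argmax_on_random_grid(self):
        import tpcfit.models as m
        rng = np.random.default_rng(42)
        old = m.DEBUG_CHECK_TPK
        m.DEBUG_CHECK_TPK = True  # coarse-grid guard active during the sweep
        try:
            for _ in range(100):
                e = rng.uniform(0.2, 1.5)
                e_d = e * rng.uniform(1.05, 20.0)
                t_h = rng.uniform(280.0, 330.0)
                p = t.SSParams(B0=1.0, E=e, E_D=e_d, T_h=t_h, T_ref=283.15)
                assert t.t_pk(p) == pytest.approx(
                    brute_force_t_pk(e, e_d, t_h), abs=1e-5)
        finally:
            m.DEBUG_CHECK_TPK = old

    def test_ppk_is_the_maximum_on_a_grid(self, canonical_params):
        grid = np.linspace(260.0, 340.0, 400)
        assert t.p_pk(canonical_params) >= np.max(
            t.ss_rate(canonical_params, grid)) - 1e-12


class TestInflation:
    def test_fold_two_at_th(self):
        p = t.SSParams(B0=1.0, E=0.6, E_D=3.0, T_h=290.0, T_ref=290.0)
        assert t.inflation_fold(p) == pytest.approx(2.0, rel=1e-12)
        assert t.log_fold_increase(p) == pytest.approx(0.0, abs=1e-9)

    def test_negligible_inflation_reports_minus_inf(self):
        p = t.SSParams(B0=1.0, E=0.6, E_D=3.0, T_h=430.0, T_ref=273.15)
        assert t.inflation_fold(p) == pytest.approx(1.0, abs=1e-10)
        assert t.log_fold_increase(p) == -math.inf

    def test_frozen_oracle_value_tref_above_th(self):
        p = t.SSParams(B0=1.0, E=0.6, E_D=2.0, T_h=280.0, T_ref=283.15)
        fold = t.inflation_fold(p)
        assert fold == pytest.approx(3.5147354260210344, rel=1e-12)
        assert fold > 2.0

    def test_monotonicity_in_th_minus_tref_and_ed(self):
        # decreasing in (T_h - T_ref) at fixed E_D
        folds = [t.inflation_fold(t.SSParams(1.0, 0.6, 2.0, 280.0 + d, 280.0))
                 for d in np.linspace(-10.0, 40.0, 25)]
        assert np.all(np.diff(folds) < 0)
        # increasing in E_D when T_ref > T_h, decreasing when T_ref < T_h
        above = [t.inflation_fold(t.SSParams(1.0, 0.1, e_d, 280.0, 285.0))
                 for e_d in np.linspace(0.5, 6.0, 12)]
        below = [t.inflation_fold(t.SSParams(1.0, 0.1, e_d, 290.0, 285.0))
                 for e_d in np.linspace(0.5, 6.0, 12)]
        assert np.all(np.diff(above) > 0) and np.all(np.diff(below) < 0)


class TestAlternatives:
    def test_ba_rate_is_b0_at_tref_and_frozen_value(self):
        assert t.ba_rate(2.5, 0.65, 283.15, 283.15) == pytest.approx(2.5, rel=1e-12)
        assert t.ba_rate(1.0, 0.0, 283.15, 310.0) == pytest.approx(1.0, rel=1e-12)
        assert t.ba_rate(1.0, 0.65, 283.15, 293.15) == pytest.approx(
            2.4812521708299986, rel=1e-12)

    def test_q10_basics_and_frozen_value(self):
        assert t.q10_estimate(1.0, 280.0, 2.0, 290.0) == pytest.approx(2.0)
        assert t.q10_estimate(1.7, 280.0, 1.7, 295.0) == pytest.approx(1.0)
        assert t.q10_estimate(0.5, 283.15, 1.8, 291.15) == pytest.approx(
            4.958817508788695, rel=1e-12)
        with pytest.raises(ValueError):
            t.q10_estimate(1.0, 280.0, 2.0, 280.0)

    def test_q10_extrapolate_identity_and_frozen_value(self):
        assert t.q10_extrapolate(3.3, 285.0, 2.1, 285.0) == pytest.approx(3.3)
        assert t.q10_extrapolate(1.0, 290.0, 2.5, 285.0) == pytest.approx(
            0.6324555320336759, rel=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(270.0, 310.0), st.floats(0.1, 5.0),
           st.floats(270.0, 310.0))
    @settings(max_examples=40, deadline=None)
    def test_q10_round_trip(self, b1, t1, b2, t2):
        if abs(t2 - t1) < 0.5:
            return
        q10 = t.q10_estimate(b1, t1, b2, t2)
        assert t.q10_extrapolate(b1, t1, q10, t2) == pytest.approx(b2, rel=1e-10)

    def test_intrinsic_optimum_oracle_and_round_trip(self):
        topt = t.intrinsic_optimum(2.0, 300.0, 0.99)
        assert topt == pytest.approx(283.1807025909787, abs=1e-8)  # bisection oracle
        assert topt < 300.0
        assert t.activity_fraction(2.0, 300.0, topt) == pytest.approx(0.99, abs=1e-10)
        # approaching level 0.5 from above pushes the optimum to T_h
        assert t.intrinsic_optimum(2.0, 300.0, 0.5 + 1e-9) == pytest.approx(
            300.0, abs=1e-3)

    @pytest.mark.parametrize("level", [0.2, 0.5, 1.0, 1.3])
    def test_intrinsic_optimum_domain(self, level):
        with pytest.raises(ValueError):
            t.intrinsic_optimum(2.0, 300.0, level)


class TestParamsValidation:
    @pytest.mark.parametrize("field,val", [
        ("B0", -1.0), ("E", 0.0), ("E_D", np.nan), ("T_h", -5.0), ("T_ref", 0.0),
    ])
    def test_invalid_fields_rejected(self, field, val):
        kw = dict(B0=1.0, E=0.6, E_D=2.0, T_h=300.0, T_ref=280.0)
        kw[field] = val
        with pytest.raises(ValueError):
            t.SSParams(**kw)

    def test_derive_recomputes_everything(self, canonical_params):
        d = t.derive(canonical_params)
        assert d.T_pk == pytest.approx(t.t_pk(canonical_params))
        assert d.P_pk == pytest.approx(t.p_pk(canonical_params))
        assert d.B_at_Tref == pytest.approx(t.b_at_tref(canonical_params))
        assert d.inflation_fold == pytest.approx(t.inflation_fold(canonical_params))
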