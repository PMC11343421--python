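"""Parametric survival families, cycle probabilities and life-table blending."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfcua.parameters import SurvivalSpec
from hfcua.survival import (
    CyclicHazardContext, DegenerateSupportError, blended_noncv_probability,
    cycle_event_probability, cycle_probability_grid,
    noncv_lifetable_probability, survival_probability,
    treatment_coef_for_hazard_ratio, trial_noncv_probability,
)

from conftest import zero_life_table


def exponential(rate: float) -> SurvivalSpec:
    return SurvivalSpec(family="exponential", intercept=math.log(rate))


ALL_FAMILIES = [
    SurvivalSpec("exponential", intercept=-3.0),
    SurvivalSpec("gompertz", intercept=-4.0, ancillary={"gamma": 0.01}),
    SurvivalSpec("weibull", intercept=4.0, ancillary={"shape": 1.3}),
    SurvivalSpec("lognormal", intercept=4.0, ancillary={"sigma": 1.1}),
    SurvivalSpec("loglogistic", intercept=4.0, ancillary={"shape": 1.4}),
    SurvivalSpec("gengamma", intercept=4.0, ancillary={"sigma": 0.9, "q": 1.2}),
    SurvivalSpec("gengamma", intercept=4.0, ancillary={"sigma": 0.9, "q": -0.7}),
]


class TestSurvivalFunction:
    @pytest.mark.parametrize("spec", ALL_FAMILIES,
                             ids=lambda s: f"{s.family}")
    def test_s0_is_one_and_nonincreasing(self, spec):
        t = np.linspace(0.0, 240.0, 400)
        s = survival_probability(spec, t)
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-14).all()
        assert ((0.0 <= s) & (s <= 1.0)).all()

    @pytest.mark.parametrize("spec", ALL_FAMILIES, ids=lambda s: s.family)
    def test_hazard_nonnegative_on_grid(self, spec):
        """-d/dt log S(t) >= 0 numerically for every family."""
        t = np.linspace(0.1, 200.0, 500)
        log_s = np.log(np.maximum(survival_probability(spec, t), 1e-300))
        assert (np.diff(log_s) <= 1e-12).all()

    def test_exponential_closed_form(self):
        spec = exponential(0.1)
        assert survival_probability(spec, 12.0) == pytest.approx(
            math.exp(-1.2), abs=1e-12)

    def test_weibull_shape_one_equals_exponential(self):
        rate = 0.05
        wei = SurvivalSpec("weibull", intercept=math.log(1.0 / rate),
                           ancillary={"shape": 1.0})
        exp = exponential(rate)
        for t in (1.0, 6.0, 24.0):
            assert survival_probability(wei, t) == pytest.approx(
                survival_probability(exp, t), abs=1e-12)

    def test_gengamma_reduces_to_weibull_at_q_one(self):
        """gengamma(mu, sigma, Q=1) == weibull(shape=1/sigma, scale=e^mu)."""
        gg = SurvivalSpec("gengamma", intercept=3.5,
                          ancillary={"sigma": 0.8, "q": 1.0})
        wei = SurvivalSpec("weibull", intercept=3.5,
                          ancillary={"shape": 1.0 / 0.8})
        t = np.array([0.5, 5.0, 50.0, 150.0])
        np.testing.assert_allclose(survival_probability(gg, t),
                                   survival_probability(wei, t), atol=1e-10)

    def test_gengamma_reduces_to_lognormal_at_q_zero(self):
        gg = SurvivalSpec("gengamma", intercept=3.5,
                          ancillary={"sigma": 1.1, "q": 0.0})
        ln = SurvivalSpec("lognormal", intercept=3.5,
                          ancillary={"sigma": 1.1})
        t = np.array([0.5, 5.0, 50.0, 150.0])
        np.testing.assert_allclose(survival_probability(gg, t),
                                   survival_probability(ln, t), atol=1e-10)

    def test_unsupported_family_named_in_error(self):
        spec = SurvivalSpec("cauchy", intercept=0.0)
        with pytest.raises(ValueError, match="cauchy"):
            survival_probability(spec, 1.0)

    def test_aft_treatment_coef_stretches_time(self):
        """A positive AFT coefficient lengthens survival."""
        spec = SurvivalSpec("weibull", intercept=4.0, treatment_coef=0.3,
                            ancillary={"shape": 1.2})
        s_trt = survival_probability(spec, 24.0, treatment=1)
        s_ref = survival_probability(spec, 24.0, treatment=0)
        assert s_trt > s_ref


class TestCycleProbability:
    def test_zero_hazard_gives_zero(self):
        spec = SurvivalSpec("exponential", intercept=-80.0)
        ctx = CyclicHazardContext(elapsed_time=10.0)
        assert cycle_event_probability(spec, ctx) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_exponential_is_memoryless(self):
        lam = 0.07
        spec = exponential(lam)
        expected = 1.0 - math.exp(-lam)
        for t in (0.0, 5.0, 123.0):
            ctx = CyclicHazardContext(elapsed_time=t)
            assert cycle_event_probability(spec, ctx) == pytest.approx(
                expected, rel=1e-12)

    def test_increasing_weibull_hazard_raises_cycle_probability(self):
        spec = SurvivalSpec("weibull", intercept=4.0,
                            ancillary={"shape": 1.5})
        p1 = cycle_event_probability(spec, CyclicHazardContext(5.0))
        p2 = cycle_event_probability(spec, CyclicHazardContext(50.0))
        assert p2 > p1
        # cross-check p2 against direct numerical conditioning
        s = survival_probability(spec, np.array([50.0, 51.0]))
        assert p2 == pytest.approx(1.0 - s[1] / s[0], rel=1e-12)

    def test_exhausted_support_raises(self):
        spec = exponential(5.0)  # S(200) underflows to 0
        with pytest.raises(DegenerateSupportError):
            cycle_event_probability(spec, CyclicHazardContext(2000.0))

    @settings(derandomize=True, max_examples=30)
    @given(shape=st.floats(0.6, 2.5), scale=st.floats(20.0, 300.0),
           n=st.integers(2, 40))
    def test_telescoping_reconstructs_survival(self, shape, scale, n):
        """Product of per-cycle survivals equals S(T) over any partition."""
        spec = SurvivalSpec("weibull", intercept=math.log(scale),
                            ancillary={"shape": shape})
        q = cycle_probability_grid(spec, n, 1.0, 0, spec.reference_state)
        reconstructed = np.prod(1.0 - q)
        assert reconstructed == pytest.approx(
            survival_probability(spec, float(n)), abs=1e-10)


class TestLifeTableBlending:
    def test_pure_cv_mortality_gives_zero_noncv(self):
        lt = zero_life_table()
        lt.table["annual_qx"] = 0.02
        lt.table["cv_share"] = 1.0
        lt2 = type(lt)(lt.table, lt.sex_mix)
        assert noncv_lifetable_probability(lt2, 70.0) == 0.0

    def test_hand_arithmetic(self):
        lt = zero_life_table()
        lt.table["annual_qx"] = 0.012
        lt.table["cv_share"] = 0.5
        lt2 = type(lt)(lt.table, {"male": 1.0})
        got = noncv_lifetable_probability(lt2, 64.0)
        assert got == pytest.approx(1.0 - 0.994 ** (1.0 / 12.0), rel=1e-12)
        assert got == pytest.approx(5.012e-4, rel=1e-3)

    def test_equal_rates_make_mix_irrelevant(self):
        lt = zero_life_table()
        lt.table["annual_qx"] = 0.03
        lt.table["cv_share"] = 0.4
        a = type(lt)(lt.table, {"male": 1.0})
        b = type(lt)(lt.table, {"male": 0.2, "female": 0.8})
        assert noncv_lifetable_probability(a, 75.0) == pytest.approx(
            noncv_lifetable_probability(b, 75.0), rel=1e-12)

    @pytest.mark.parametrize("trial,table,expected", [
        (0.001, 0.003, 0.003),  # general population dominates
        (0.004, 0.003, 0.004),  # trial estimate dominates
        (0.002, 0.002, 0.002),  # tie
    ])
    def test_blend_takes_maximum(self, trial, table, expected):
        assert blended_noncv_probability(trial, table) == expected

    def test_trial_noncv_is_difference(self):
        ac = exponential(0.010050335853501441)   # 1-e^-x = 0.010
        cv = exponential(0.004008021397538822)   # 1-e^-x = 0.004
        got = trial_noncv_probability(ac, cv, CyclicHazardContext(0.0))
        assert got == pytest.approx(0.006, rel=1e-9)

    def test_identical_specs_give_zero(self):
        spec = exponential(0.01)
        assert trial_noncv_probability(spec, spec,
                                       CyclicHazardContext(3.0)) == 0.0

    def test_crossing_curves_floor_at_zero_with_warning(self, caplog):
        ac = exponential(0.004)
        cv = exponential(0.010)
        import logging
        with caplog.at_level(logging.WARNING, logger="hfcua.survival"):
            got = trial_noncv_probability(ac, cv, CyclicHazardContext(0.0))
        assert got == 0.0
        assert any("floored" in r.message for r in caplog.records)


class TestHazardRatioMapping:
    def test_ph_families_log_hr(self):
        spec = exponential(0.01)
        assert treatment_coef_for_hazard_ratio(spec, 0.8) == pytest.approx(
            math.log(0.8))

    def test_weibull_mapping_reproduces_hr(self):
        spec = SurvivalSpec("weibull", intercept=4.0,
                            ancillary={"shape": 1.4})
        hr = 0.75
        coef = treatment_coef_for_hazard_ratio(spec, hr)
        spec.treatment_coef = coef
        # cumulative-hazard ratio at any t must equal hr for Weibull PH
        for t in (6.0, 60.0):
            h1 = -math.log(survival_probability(spec, t, treatment=1))
            h0 = -math.log(survival_probability(spec, t, treatment=0))
            assert h1 / h0 == pytest.approx(hr, rel=1e-10)

    def test_null_ratio_is_zero_for_any_family(self):
        for spec in ALL_FAMILIES:
            assert treatment_coef_for_hazard_ratio(spec, 1.0) == 0.0

    def test_no_exact_mapping_rejected(self):
        spec = SurvivalSpec("lognormal", intercept=4.0,
                            ancillary={"sigma": 1.0})
        with pytest.raises(ValueError, match="lognormal"):
            treatment_coef_for_hazard_ratio(spec, 0.8)
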