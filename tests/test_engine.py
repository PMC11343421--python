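"""Cohort propagation, accrual arithmetic and the microsimulation oracle."""

import math

import numpy as np
import pytest

from hfcua import engine
from hfcua.engine import (CohortTrace, accrue_outcomes, discount_factor,
                          expected_hhf_events, mean_time_on_treatment,
                          run_arm, run_cohort)
from hfcua.parameters import ALIVE_STATES, EventRateModel, SurvivalSpec

from conftest import make_deathless, null_treatment_effects
from helpers import microsim_se, microsimulate


class TestDiscountFactor:
    def test_zero_rate_is_unity_everywhere(self):
        for k in (0, 7, 120):
            assert discount_factor(0.0, k) == 1.0

    def test_closed_forms(self):
        assert discount_factor(0.03, 0) == 1.0
        assert discount_factor(0.03, 12) == pytest.approx(1 / 1.03, rel=1e-12)
        assert discount_factor(0.03, 6) == pytest.approx(1.03 ** -0.5,
                                                         rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


class TestExpectedEvents:
    def test_zero_occupancy_gives_zero(self):
        model = EventRateModel(intercept=math.log(0.01))
        assert expected_hhf_events(model, np.zeros(4), 0) == 0.0

    def test_hand_arithmetic(self):
        model = EventRateModel(intercept=math.log(0.007),
                               state_coefs={"Q1": math.log(1.5)})
        got = expected_hhf_events(model, np.array([1.0, 0, 0, 0]), 0)
        assert got == pytest.approx(0.0105, rel=1e-12)

    def test_null_treatment_effect_equalises_arms(self):
        model = EventRateModel(intercept=math.log(0.006), treatment_coef=0.0,
                               state_coefs={"Q1": 0.4})
        occ = np.array([0.3, 0.3, 0.2, 0.2])
        assert expected_hhf_events(model, occ, 1) == \
            expected_hhf_events(model, occ, 0)


class TestCohortPropagation:
    def test_deathless_identity_cohort_is_static(self, bundle):
        """No mortality + identity matrices: occupancy frozen, 1 LY/year."""
        b = make_deathless(bundle, horizon=12)
        trace = run_cohort(b, "SOC")
        assert trace.n_cycles == 12
        np.testing.assert_allclose(trace.occupancy[-1, 4:8], 0.25, atol=1e-12)
        summary = accrue_outcomes(trace, b, "SOC")
        assert summary.undiscounted.ly_total == pytest.approx(1.0, abs=1e-10)

    def test_constant_hazard_life_expectancy(self, bundle):
        """Single constant monthly death probability: LY -> 1/(12q)."""
        q = 0.01
        b = make_deathless(bundle, horizon="lifetime")
        b.economics.half_cycle_correction = False
        b.all_cause_death = SurvivalSpec(
            family="exponential", intercept=math.log(-math.log(1 - q)))
        b.cv_death = SurvivalSpec(family="exponential", intercept=-80.0)
        trace = run_cohort(b, "SOC")
        summary = accrue_outcomes(trace, b, "SOC")
        assert summary.undiscounted.ly_total == pytest.approx(
            1.0 / q / 12.0, rel=1e-3)

    def test_probability_conservation_and_dead_monotone(self, base_bundle):
        for arm in ("EPG_SOC", "SOC"):
            trace = run_cohort(base_bundle, arm)
            totals = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(totals, 1.0, atol=1e-9)
            assert (np.diff(trace.occupancy[:, 8]) >= -1e-15).all()
            assert (np.diff(trace.occupancy[:, 9]) >= -1e-15).all()

    def test_comparator_arm_has_no_on_treatment_mass(self, base_bundle):
        trace = run_cohort(base_bundle, "SOC")
        assert trace.occupancy[:, 0:4].sum() == 0.0

    def test_unknown_arm_rejected(self, base_bundle):
        with pytest.raises(ValueError, match="arm"):
            run_cohort(base_bundle, "PLACEBO")

    def test_occupancy_matches_microsimulation(self, bundle):
        """Cohort expectations agree with a walker-level stochastic oracle."""
        b = bundle
        b.economics.horizon = 60
        n_walkers = 200_000
        sim = microsimulate(b, "EPG_SOC", 60, n_walkers, seed=20240823)
        trace = run_cohort(b, "EPG_SOC")
        for cycle in (6, 12, 60):
            se = microsim_se(trace.occupancy[cycle], n_walkers)
            diff = np.abs(sim[cycle] - trace.occupancy[cycle])
            assert (diff <= 3.0 * se + 1e-12).all(), (
                f"cycle {cycle}: |diff|/se = {diff / se}"
            )


class TestAccrual:
    def _manual_trace(self, hhf=0.0):
        occ = np.zeros((2, 10))
        occ[:, 4] = 1.0  # one full cycle in Q1, off treatment
        return CohortTrace(
            arm="SOC", occupancy=occ, hhf_events=np.array([hhf]),
            ae_events={}, cv_deaths=np.zeros(1), noncv_deaths=np.zeros(1),
            discontinuations=np.zeros(1), ages=np.array([64.6]))

    def test_one_cycle_in_q1_yields_published_utility_slice(self, base_bundle):
        trace = self._manual_trace()
        s = accrue_outcomes(trace, base_bundle, "SOC")
        assert s.undiscounted.qaly_by_state["Q1"] == pytest.approx(
            0.613 / 12.0, rel=1e-12)

    def test_one_hhf_event_costs_and_disutility(self, base_bundle):
        """A hospitalisation at cycle 0 loses 0.335 QALYs and RM 5,276."""
        trace = self._manual_trace(hhf=1.0)
        s = accrue_outcomes(trace, base_bundle, "SOC")
        assert s.discounted.qaly_loss_hhf == pytest.approx(-0.335, rel=1e-12)
        assert s.discounted.cost_hhf == pytest.approx(5276.0, rel=1e-12)

    def test_costs_are_homogeneous_of_degree_one(self, bundle, base_bundle):
        base = run_arm(base_bundle, "EPG_SOC")
        b = bundle
        b.costs.hhf_cost *= 2
        b.costs.cv_death_cost *= 2
        b.costs.noncv_death_cost *= 2
        b.costs.monthly_disease_mgmt_cost *= 2
        for arm in b.costs.monthly_drug_cost:
            b.costs.monthly_drug_cost[arm] *= 2
        for ev in b.adverse_events.events.values():
            ev.unit_cost *= 2
        doubled = run_arm(b, "EPG_SOC")
        for attr in ("cost_drug", "cost_hhf", "cost_cv_death", "cost_ae",
                     "cost_disease_mgmt", "cost_total"):
            assert getattr(doubled.discounted, attr) == pytest.approx(
                2.0 * getattr(base.discounted, attr), rel=1e-12)

    def test_zero_discount_reproduces_undiscounted(self, bundle):
        b = bundle
        b.economics.annual_discount_rate_cost = 0.0
        b.economics.annual_discount_rate_benefit = 0.0
        s = run_arm(b, "SOC")
        assert s.discounted.ly_total == s.undiscounted.ly_total
        assert s.discounted.cost_total == s.undiscounted.cost_total

    def test_discounted_below_undiscounted(self, base_bundle):
        s = run_arm(base_bundle, "EPG_SOC")
        assert s.discounted.ly_total < s.undiscounted.ly_total
        assert s.discounted.cost_total < s.undiscounted.cost_total
        assert s.discounted.qaly_total <= s.discounted.ly_total

    def test_category_costs_sum_to_total(self, base_bundle):
        s = run_arm(base_bundle, "EPG_SOC")
        d = s.discounted
        assert d.cost_total == pytest.approx(
            d.cost_drug + d.cost_hhf + d.cost_cv_death + d.cost_noncv_death
            + d.cost_ae + d.cost_disease_mgmt, rel=1e-12)

    def test_half_cycle_ly_between_start_and_end_sums(self, base_bundle):
        trace = run_cohort(base_bundle, "SOC")
        start = trace.occupancy[:-1, :8].sum() / 12.0
        end = trace.occupancy[1:, :8].sum() / 12.0
        s = accrue_outcomes(trace, base_bundle, "SOC")
        assert end < s.undiscounted.ly_total < start


class TestNullEffects:
    def test_null_effects_leave_only_drug_cost_delta(self, bundle):
        """Arms identical except drug price: dQALY = dLY = 0 and the cost
        increment is exactly the drug-cost increment."""
        b = null_treatment_effects(bundle)
        sa = run_arm(b, "EPG_SOC")
        sb = run_arm(b, "SOC")
        assert sa.discounted.qaly_total == pytest.approx(
            sb.discounted.qaly_total, abs=1e-10)
        assert sa.discounted.ly_total == pytest.approx(
            sb.discounted.ly_total, abs=1e-10)
        dcost = sa.discounted.cost_total - sb.discounted.cost_total
        ddrug = sa.discounted.cost_drug - sb.discounted.cost_drug
        assert dcost == pytest.approx(ddrug, abs=1e-9)
        assert ddrug > 0


class TestTimeOnTreatment:
    def test_no_discontinuation_no_death(self, bundle):
        b = make_deathless(bundle, horizon=24)
        trace = run_cohort(b, "EPG_SOC")
        assert mean_time_on_treatment(trace, b) == pytest.approx(2.0,
                                                                 abs=1e-10)

    def test_constant_discontinuation_geometric_limit(self, bundle):
        d = 0.02
        b = make_deathless(bundle, horizon="lifetime")
        b.economics.half_cycle_correction = False
        b.discontinuation = SurvivalSpec(
            family="exponential", intercept=math.log(-math.log(1 - d)))
        trace = run_cohort(b, "EPG_SOC")
        assert mean_time_on_treatment(trace, b) == pytest.approx(
            1.0 / d / 12.0, rel=1e-3)

    def test_comparator_arm_is_zero(self, base_bundle):
        trace = run_cohort(base_bundle, "SOC")
        assert mean_time_on_treatment(trace, base_bundle) == 0.0


class TestTraceExport:
    def test_trace_round_trips_to_csv(self, short_bundle, tmp_path):
        import pandas as pd
        trace = run_cohort(short_bundle, "EPG_SOC")
        path = tmp_path / "trace.csv"
        trace.export(path)
        df = pd.read_csv(path)
        assert len(df) == trace.n_cycles + 1
        assert df["dead_cv"].iloc[-1] == pytest.approx(
            trace.occupancy[-1, 8], rel=1e-12)
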