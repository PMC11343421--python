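"""Cohort propagation, accrual, discounting and outcome summaries.

The cohort lives on a 10-dimensional occupancy vector: the four KCCQ-CSS
quartile states crossed with on/off intervention status, plus CV death and
non-CV death.  The comparator arm carries all mass in the off-treatment
layer.  Within every monthly cycle, in fixed order:

1. death — CV first (parametric risk equation), then blended non-CV
   applied to the CV survivors;
2. treatment discontinuation (intervention arm, on-treatment layer only);
   discontinued patients move to the matching off-treatment state and from
   then on face comparator risks, costs and utilities;
3. transition among alive states with the period- and treatment-status-
   appropriate matrix;
4. transient events (heart-failure hospitalisations, adverse events)
   accrue as expected counts on the post-death alive occupancy.

State-based quantities (life-years, state utilities, drug and disease-
management cost) are half-cycle corrected — the mean of cycle-start and
cycle-end occupancy — while event-based quantities apply in full in their
cycle.  Discounting is continuous-in-cycles: (1+r)^(-cycle/12).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (ALIVE_STATES, ARMS, EventRateModel, ModelParameters)
from . import survival as surv

log = logging.getLogger(__name__)

N_ALIVE = 4
IDX_ON = slice(0, 4)
IDX_OFF = slice(4, 8)
IDX_DEAD_CV = 8
IDX_DEAD_NONCV = 9

ALIVE_TOL = 1e-6  # lifetime horizon stops below this total alive occupancy


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Per-cycle record of occupancy and expected events for one arm."""

    arm: str
    occupancy: np.ndarray          # (n_cycles + 1, 10)
    hhf_events: np.ndarray         # (n_cycles,)
    ae_events: dict[str, np.ndarray]
    cv_deaths: np.ndarray
    noncv_deaths: np.ndarray
    discontinuations: np.ndarray
    ages: np.ndarray               # age at cycle start, (n_cycles,)
    cycle_length: float = 1.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self, cycle: int) -> float:
        return float(self.occupancy[cycle, :8].sum())

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}_on" for s in ALIVE_STATES] + \
               [f"{s}_off" for s in ALIVE_STATES] + ["dead_cv", "dead_noncv"]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        ev = pd.DataFrame({
            "hhf_events": np.append(self.hhf_events, np.nan),
            "cv_deaths": np.append(self.cv_deaths, np.nan),
            "noncv_deaths": np.append(self.noncv_deaths, np.nan),
            "discontinuations": np.append(self.discontinuations, np.nan),
            "age": np.append(self.ages, np.nan),
        })
        for name, arr in self.ae_events.items():
            ev[f"ae_{name}"] = np.append(arr, np.nan)
        return pd.concat([df, ev], axis=1)

    def export(self, path: str | pathlib.Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def discount_factor(annual_rate: float, cycle_index: float) -> float:
    """(1 + r)^(-cycle/12); equals 1 at cycle 0 and for r = 0."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_index / 12.0)


def expected_hhf_events(
    rate_model: EventRateModel,
    occupancy: np.ndarray | dict[str, float],
    treatment_status: int,
) -> float:
    """Expected hospitalisation count for one cycle's alive occupancy.

    Sum over states of occupancy times exp(intercept + b_trt * on +
    b_state); an expected-count (Poisson) accounting with no per-patient
    cap.
    """
    if isinstance(occupancy, dict):
        occ = np.array([occupancy.get(s, 0.0) for s in ALIVE_STATES])
    else:
        occ = np.asarray(occupancy, dtype=float)
    rates = np.array([rate_model.monthly_rate(treatment_status, s)
                      for s in ALIVE_STATES])
    return float(occ @ rates)


def _horizon_cycles(p: ModelParameters) -> int:
    e = p.economics
    lifetime_cap = int(math.ceil((e.max_age - e.starting_age) * 12.0))
    if e.horizon == "lifetime":
        n = lifetime_cap
    else:
        n = int(e.horizon)
        if n > lifetime_cap:
            log.warning("horizon %d months exceeds age cap; clamped to %d",
                        n, lifetime_cap)
            n = lifetime_cap
    # never look up ages beyond the life table
    table_cap = int((p.life_table.max_age + 1 - e.starting_age) * 12.0)
    if n > table_cap:
        log.warning("horizon exceeds life-table range; clamped to %d cycles",
                    table_cap)
        n = table_cap
    return n


# ---------------------------------------------------------------------------
# Cohort propagation
# ---------------------------------------------------------------------------


def run_cohort(p: ModelParameters, arm: str) -> CohortTrace:
    """Propagate the cohort for one arm and record the full trace.

    The cohort starts 25% in each quartile state, on treatment in the
    intervention arm and off in the comparator.  A "lifetime" horizon runs
    to the configured maximum age or until total alive occupancy falls
    below 1e-6.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    e = p.economics
    n_max = _horizon_cycles(p)
    dt = e.cycle_length_months

    # per-cycle conditional probabilities, precomputed per stratum
    p_cv = np.empty((n_max, N_ALIVE, 2))
    p_ac = np.empty((n_max, N_ALIVE, 2))
    for j, s in enumerate(ALIVE_STATES):
        for trt in (0, 1):
            p_cv[:, j, trt] = surv.cycle_probability_grid(
                p.cv_death, n_max, dt, trt, s)
            p_ac[:, j, trt] = surv.cycle_probability_grid(
                p.all_cause_death, n_max, dt, trt, s)
    if p.discontinuation is not None and arm == "EPG_SOC":
        p_disc = np.stack([
            surv.cycle_probability_grid(p.discontinuation, n_max, dt, 1, s)
            for s in ALIVE_STATES
        ], axis=1)
    else:
        p_disc = np.zeros((n_max, N_ALIVE))

    trial_noncv = np.maximum(0.0, p_ac - p_cv)
    if (p_cv > p_ac).any():
        log.debug(
            "arm %s: CV-death probability exceeds all-cause in %d stratum-"
            "cycles; trial-based non-CV floored at 0", arm,
            int((p_cv > p_ac).sum()),
        )

    ages = e.starting_age + np.arange(n_max) * dt / 12.0
    lt_noncv = np.array([
        surv.noncv_lifetable_probability(p.life_table, a) for a in ages
    ])
    p_noncv = np.maximum(trial_noncv, lt_noncv[:, None, None])

    # AE monthly rates: on-treatment uses intervention-arm rates
    active_aes = p.adverse_events.active()
    ae_on = {n: ev.monthly_rate["EPG_SOC" if arm == "EPG_SOC" else "SOC"]
             for n, ev in active_aes.items()}
    ae_off = {n: ev.monthly_rate["SOC"] for n, ev in active_aes.items()}

    hhf_on = np.array([p.hhf.monthly_rate(1, s) for s in ALIVE_STATES])
    hhf_off = np.array([p.hhf.monthly_rate(0, s) for s in ALIVE_STATES])

    occ = np.zeros((n_max + 1, 10))
    start = np.full(N_ALIVE, 0.25)
    if arm == "EPG_SOC":
        occ[0, IDX_ON] = start
    else:
        occ[0, IDX_OFF] = start

    hhf_events = np.zeros(n_max)
    cv_deaths = np.zeros(n_max)
    noncv_deaths = np.zeros(n_max)
    discontinuations = np.zeros(n_max)
    ae_events = {n: np.zeros(n_max) for n in active_aes}

    n_run = n_max
    for k in range(n_max):
        on = occ[k, IDX_ON].copy()
        off = occ[k, IDX_OFF].copy()

        # 1. deaths: CV first, then blended non-CV on CV survivors
        cv_on, cv_off = p_cv[k, :, 1], p_cv[k, :, 0]
        nc_on, nc_off = p_noncv[k, :, 1], p_noncv[k, :, 0]
        cvd = on @ cv_on + off @ cv_off
        surv_on = on * (1.0 - cv_on)
        surv_off = off * (1.0 - cv_off)
        ncvd = surv_on @ nc_on + surv_off @ nc_off
        surv_on *= 1.0 - nc_on
        surv_off *= 1.0 - nc_off

        # 2. discontinuation (on-treatment layer only)
        moved = surv_on * p_disc[k]
        surv_on = surv_on - moved
        surv_off = surv_off + moved

        # 3. transitions among alive states
        period = p.transitions.period_for_cycle(k)
        m_on = p.transitions.matrices[("EPG_SOC", period)]
        m_off = p.transitions.matrices[("SOC", period)]
        new_on = surv_on @ m_on
        new_off = surv_off @ m_off

        # 4. transient events on post-death alive occupancy
        hhf_events[k] = new_on @ hhf_on + new_off @ hhf_off
        on_total, off_total = new_on.sum(), new_off.sum()
        for name in active_aes:
            ae_events[name][k] = on_total * ae_on[name] + off_total * ae_off[name]

        occ[k + 1, IDX_ON] = new_on
        occ[k + 1, IDX_OFF] = new_off
        occ[k + 1, IDX_DEAD_CV] = occ[k, IDX_DEAD_CV] + cvd
        occ[k + 1, IDX_DEAD_NONCV] = occ[k, IDX_DEAD_NONCV] + ncvd
        cv_deaths[k] = cvd
        noncv_deaths[k] = ncvd
        discontinuations[k] = moved.sum()

        if e.horizon == "lifetime" and on_total + off_total < ALIVE_TOL:
            n_run = k + 1
            break

    sl = slice(0, n_run)
    return CohortTrace(
        arm=arm,
        occupancy=occ[: n_run + 1],
        hhf_events=hhf_events[sl],
        ae_events={n: a[sl] for n, a in ae_events.items()},
        cv_deaths=cv_deaths[sl],
        noncv_deaths=noncv_deaths[sl],
        discontinuations=discontinuations[sl],
        ages=ages[sl],
        cycle_length=dt,
    )


# ---------------------------------------------------------------------------
# Accrual
# ---------------------------------------------------------------------------


@dataclass
class Accrual:
    """LY/QALY/cost totals at one discount setting."""

    ly_total: float = 0.0
    ly_by_state: dict[str, float] = field(default_factory=dict)
    qaly_total: float = 0.0
    qaly_by_state: dict[str, float] = field(default_factory=dict)
    qaly_loss_hhf: float = 0.0   # reported negative
    qaly_loss_ae: float = 0.0    # reported negative
    cost_drug: float = 0.0
    cost_hhf: float = 0.0
    cost_cv_death: float = 0.0
    cost_noncv_death: float = 0.0
    cost_ae: float = 0.0
    cost_disease_mgmt: float = 0.0

    @property
    def cost_total(self) -> float:
        return (self.cost_drug + self.cost_hhf + self.cost_cv_death +
                self.cost_noncv_death + self.cost_ae + self.cost_disease_mgmt)


@dataclass
class OutcomeSummary:
    """Discounted and undiscounted totals, event rates and counts for one arm."""

    arm: str
    discounted: Accrual
    undiscounted: Accrual
    event_rates_per_100py: dict[str, float]
    event_totals: dict[str, float]
    years_on_treatment: float
    person_years: float
    n_cycles: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["discounted"]["cost_total"] = self.discounted.cost_total
        d["undiscounted"]["cost_total"] = self.undiscounted.cost_total
        return d

    def to_json(self, path: str | pathlib.Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text, encoding="utf-8")
        return text


def _accrue(trace: CohortTrace, p: ModelParameters, arm: str,
            rate_cost: float, rate_benefit: float) -> Accrual:
    n = trace.n_cycles
    k = np.arange(n)
    db = (1.0 + rate_benefit) ** (-k / 12.0)
    dc = (1.0 + rate_cost) ** (-k / 12.0)

    occ = trace.occupancy
    if p.economics.half_cycle_correction:
        mid = 0.5 * (occ[:-1] + occ[1:])
    else:
        mid = occ[:-1]
    mid_on = mid[:, IDX_ON]
    mid_off = mid[:, IDX_OFF]
    mid_state = mid_on + mid_off          # (n, 4) alive occupancy by state
    mid_alive = mid_state.sum(axis=1)
    on_total = mid_on.sum(axis=1)
    off_total = mid_off.sum(axis=1)
    months = trace.cycle_length

    a = Accrual()
    u = p.utilities
    c = p.costs
    frac = months / 12.0

    a.ly_by_state = {
        s: float(db @ mid_state[:, j]) * frac for j, s in enumerate(ALIVE_STATES)
    }
    a.ly_total = sum(a.ly_by_state.values())
    a.qaly_by_state = {
        s: a.ly_by_state[s] * u.state_utility[s] for s in ALIVE_STATES
    }
    hhf_loss_per_event = (abs(u.hhf_disutility) *
                          u.hhf_disutility_duration_months / 12.0)
    a.qaly_loss_hhf = -float(db @ trace.hhf_events) * hhf_loss_per_event
    ae_loss = 0.0
    ae_cost = 0.0
    active = p.adverse_events.active()
    for name, ev_counts in trace.ae_events.items():
        spec = active[name]
        ae_loss += (float(db @ ev_counts) * abs(spec.disutility) *
                    spec.disutility_duration_months / 12.0)
        ae_cost += float(dc @ ev_counts) * spec.unit_cost
    a.qaly_loss_ae = -ae_loss
    a.qaly_total = (sum(a.qaly_by_state.values()) + a.qaly_loss_hhf +
                    a.qaly_loss_ae)

    drug_on = c.monthly_drug_cost["EPG_SOC"] if arm == "EPG_SOC" else \
        c.monthly_drug_cost["SOC"]
    drug_off = c.monthly_drug_cost["SOC"]
    a.cost_drug = float(dc @ (on_total * drug_on + off_total * drug_off)) * months
    a.cost_disease_mgmt = float(dc @ mid_alive) * c.monthly_disease_mgmt_cost * months
    a.cost_hhf = float(dc @ trace.hhf_events) * c.hhf_cost
    a.cost_cv_death = float(dc @ trace.cv_deaths) * c.cv_death_cost
    a.cost_noncv_death = float(dc @ trace.noncv_deaths) * c.noncv_death_cost
    a.cost_ae = ae_cost
    return a


def mean_time_on_treatment(trace: CohortTrace, p: ModelParameters) -> float:
    """Mean undiscounted years on the intervention (0 for the comparator)."""
    if trace.arm != "EPG_SOC":
        return 0.0
    occ = trace.occupancy
    if p.economics.half_cycle_correction:
        mid_on = 0.5 * (occ[:-1, IDX_ON] + occ[1:, IDX_ON])
    else:
        mid_on = occ[:-1, IDX_ON]
    return float(mid_on.sum()) * trace.cycle_length / 12.0


def accrue_outcomes(trace: CohortTrace, p: ModelParameters, arm: str) -> OutcomeSummary:
    """Turn a trace into discounted/undiscounted totals and event rates.

    Event rates per 100 person-years use undiscounted totals:
    100 * events / alive person-years.
    """
    e = p.economics
    disc = _accrue(trace, p, arm, e.annual_discount_rate_cost,
                   e.annual_discount_rate_benefit)
    undisc = _accrue(trace, p, arm, 0.0, 0.0)

    py = undisc.ly_total
    totals = {
        "hhf": float(trace.hhf_events.sum()),
        "cv_death": float(trace.cv_deaths.sum()),
        "noncv_death": float(trace.noncv_deaths.sum()),
        "discontinuation": float(trace.discontinuations.sum()),
    }
    for name, arr in trace.ae_events.items():
        totals[f"ae_{name}"] = float(arr.sum())
    totals["ae_aggregate"] = sum(v for k, v in totals.items()
                                 if k.startswith("ae_") and k != "ae_aggregate")
    rates = {k: (100.0 * v / py if py > 0 else 0.0) for k, v in totals.items()
             if k != "discontinuation"}

    return OutcomeSummary(
        arm=arm,
        discounted=disc,
        undiscounted=undisc,
        event_rates_per_100py=rates,
        event_totals=totals,
        years_on_treatment=mean_time_on_treatment(trace, p),
        person_years=py,
        n_cycles=trace.n_cycles,
    )


def run_arm(p: ModelParameters, arm: str) -> OutcomeSummary:
    """Convenience: propagate one arm and accrue its outcomes."""
    return accrue_outcomes(run_cohort(p, arm), p, arm)
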