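"""Synthetic parameter bundles emulating the trial-derived model inputs.

The fitted coefficient tables behind the published model (health-state
transition matrices, Poisson hospitalisation model, parametric mortality
and discontinuation equations, adverse-event rates) are not publicly
deposited.  This module generates complete, internally consistent
stand-ins so the rest of the engine is fully exercisable: row-stochastic
matrices with a treatment-favourable drift, Weibull mortality and
generalised-gamma discontinuation equations, a Gompertz-like life table,
and the published cost/utility inputs verbatim.  Root-finding calibration
then pins the generated risk equations to the published whole-model event
rates (per 100 person-years) and mean treatment duration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import engine
from .parameters import (
    ALIVE_STATES, ARMS, PERIODS, AE_NAMES, KETOACIDOSIS,
    AdverseEvent, AdverseEventProfile, CombineSpec, CostSet, EconomicConfig,
    EventRateModel, LifeTable, ModelParameters, SurvivalSpec,
    TransitionSchedule, TreatmentEffect, default_health_states,
    require_valid,
)

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    pass


class GenerationError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Targets and knobs for one synthetic parameter bundle.

    Default event-rate targets (per 100 person-years) and the mean years
    on treatment are the published base-case values for the comparator and
    intervention arms.
    """

    seed: int = 0
    target_soc_hhf_rate: float = 8.45
    target_epg_hhf_rate: float = 7.31
    target_soc_cv_death_rate: float = 5.12
    target_epg_cv_death_rate: float = 4.84
    target_soc_noncv_rate: float = 11.11
    target_mean_years_on_treatment: float = 3.34
    state_drift: float = 1.0       # scale of the intervention's matrix shift
    starting_age: float = 64.6

    def validate(self) -> None:
        for name in ("target_soc_hhf_rate", "target_epg_hhf_rate",
                     "target_soc_cv_death_rate", "target_epg_cv_death_rate",
                     "target_soc_noncv_rate",
                     "target_mean_years_on_treatment"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be > 0")
        if self.target_epg_hhf_rate > self.target_soc_hhf_rate:
            raise GenerationError("intervention hHF target exceeds comparator")
        if self.target_epg_cv_death_rate > self.target_soc_cv_death_rate:
            raise GenerationError("intervention CV-death target exceeds comparator")


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


def generate_lifetable(seed: int, max_age: int = 100,
                       min_age: int = 40) -> LifeTable:
    """Synthetic general-population life table with a CV-death share.

    Annual all-cause mortality follows a Gompertz law with a small seeded
    multiplicative jitter (monotonicity enforced); the CV share of deaths
    declines with age within a 0.2-0.5 band.  Not a transcription of any
    national life table.
    """
    if max_age < 100:
        raise GenerationError("max_age must be >= 100")
    rng = np.random.default_rng(seed)
    ages = np.arange(min_age, max_age + 1)
    rows = []
    for sex, scale in (("male", 1.0), ("female", 0.78)):
        qx = 3.4e-5 * scale * np.exp(0.094 * ages)
        qx *= np.exp(rng.normal(0.0, 0.02, size=qx.shape))
        qx = np.minimum(np.maximum.accumulate(qx), 1.0)
        cv = np.clip(0.45 - 0.0025 * (ages - min_age), 0.2, 0.5)
        rows.append(pd.DataFrame({
            "age": ages, "sex": sex, "annual_qx": qx, "cv_share": cv,
        }))
    table = pd.concat(rows, ignore_index=True)
    return LifeTable(table, sex_mix={"male": 0.55, "female": 0.45})


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

#: monthly movement propensity by period: most change in months 1-3
#: (health-status response has early inflection points), settling later.
_PERIOD_MOBILITY = {"m1_3": 1.5, "m4_8": 1.0, "m9plus": 0.7}
_PERIOD_DRIFT = {"m1_3": 0.22, "m4_8": 0.12, "m9plus": 0.06}
_DIRICHLET_CONC = 600.0


def _base_row(i: int, mobility: float) -> np.ndarray:
    """Mean-reverting comparator row for from-state index i (0 = worst)."""
    row = np.zeros(4)
    stay = 1.0 - 0.38 * mobility
    row[i] = stay
    move = 1.0 - stay
    # slight downward (disease-progression) tilt: 55/45 toward worse states
    weights = np.zeros(4)
    for j in range(4):
        if j == i:
            continue
        dist = abs(j - i)
        w = 0.22 ** (dist - 1)
        w *= 0.55 if j < i else 0.45
        weights[j] = w
    row += move * weights / weights.sum()
    return row / row.sum()


def _generate_matrices(rng: np.random.Generator,
                       drift: float) -> dict[tuple[str, str], np.ndarray]:
    matrices: dict[tuple[str, str], np.ndarray] = {}
    for period in PERIODS:
        soc = np.empty((4, 4))
        for i in range(4):
            centre = _base_row(i, _PERIOD_MOBILITY[period])
            soc[i] = rng.dirichlet(_DIRICHLET_CONC * centre)
        matrices[("SOC", period)] = soc
        # intervention: fixed log-odds shift toward better states
        delta = _PERIOD_DRIFT[period] * drift
        tilt = np.exp(delta * np.arange(4))
        epg = soc * tilt[None, :]
        epg /= epg.sum(axis=1, keepdims=True)
        matrices[("EPG_SOC", period)] = epg
    return matrices


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

#: published per-100-PY adverse-event rates (intervention, comparator) and
#: per-event disutilities / unit costs (RM).
_AE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "urinary_tract_infection": (5.08, 4.53, -0.040, 213.0),
    "genital_infection": (0.82, 0.39, -0.038, 320.0),
    "acute_renal_failure": (7.05, 7.26, -0.013, 3185.0),
    "hepatic_injury": (2.43, 2.84, -0.042, 3230.0),
    "volume_depletion": (6.13, 5.38, -0.026, 984.0),
    "hypotension": (5.38, 4.80, -0.025, 1282.0),
    "hypoglycaemia": (1.36, 1.41, -0.002, 693.0),
    "bone_fracture": (2.37, 2.30, -0.156, 3523.0),
    # scenario-only event (rate < 1 per 100 PY); synthetic assumptions
    KETOACIDOSIS: (0.50, 0.20, -0.050, 3000.0),
}

_STATE_UTILITIES = {"Q1": 0.613, "Q2": 0.707, "Q3": 0.778, "Q4": 0.832}


def generate_bundle(spec: SyntheticSpec) -> ModelParameters:
    """Generate an uncalibrated but valid synthetic parameter bundle."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    transitions = TransitionSchedule(_generate_matrices(rng, spec.state_drift))

    # Poisson hHF risk equation: log monthly rate, reference state Q4.
    hhf = EventRateModel(
        intercept=math.log(spec.target_soc_hhf_rate / 1200.0) - 0.35,
        treatment_coef=math.log(max(
            spec.target_epg_hhf_rate / spec.target_soc_hhf_rate, 1e-6)),
        state_coefs={"Q1": math.log(1.8), "Q2": math.log(1.4),
                     "Q3": math.log(1.15)},
    )

    # Weibull AFT mortality; worse states die sooner (negative log-time).
    cv_death = SurvivalSpec(
        family="weibull", intercept=5.4, treatment_coef=0.05,
        state_coefs={"Q1": -0.5, "Q2": -0.3, "Q3": -0.15},
        ancillary={"shape": 1.1},
    )
    all_cause_death = SurvivalSpec(
        family="weibull", intercept=4.3, treatment_coef=0.0,
        state_coefs={"Q1": -0.5, "Q2": -0.3, "Q3": -0.15},
        ancillary={"shape": 1.15},
    )
    # generalised-gamma time to treatment discontinuation
    discontinuation = SurvivalSpec(
        family="gengamma", intercept=3.8, treatment_coef=0.0,
        state_coefs={"Q1": -0.2, "Q2": -0.1, "Q3": -0.05},
        ancillary={"sigma": 0.9, "q": 1.2},
    )

    events = {
        name: AdverseEvent(
            name=name,
            monthly_rate={"EPG_SOC": epg / 1200.0, "SOC": soc / 1200.0},
            disutility=dis, unit_cost=cost,
        )
        for name, (epg, soc, dis, cost) in _AE_TABLE.items()
    }
    adverse_events = AdverseEventProfile(events, include_ketoacidosis=False)

    costs = CostSet(
        monthly_drug_cost={"EPG_SOC": 212.0, "SOC": 101.0},
        hhf_cost=5276.0, cv_death_cost=2573.0, noncv_death_cost=0.0,
        monthly_disease_mgmt_cost=28.0,
    )
    from .parameters import UtilityModel
    utilities = UtilityModel(state_utility=dict(_STATE_UTILITIES))
    economics = EconomicConfig(starting_age=spec.starting_age)
    life_table = generate_lifetable(spec.seed)

    bundle = ModelParameters(
        states=default_health_states(), transitions=transitions, hhf=hhf,
        cv_death=cv_death, all_cause_death=all_cause_death,
        discontinuation=discontinuation, adverse_events=adverse_events,
        costs=costs, utilities=utilities, economics=economics,
        life_table=life_table, treatment_effect=TreatmentEffect(),
        combine=CombineSpec(),
    )
    return require_valid(bundle)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def modelled_rate(bundle: ModelParameters, event: str, arm: str) -> float:
    """Whole-model event rate per 100 person-years for one arm."""
    summary = engine.run_arm(bundle, arm)
    return summary.event_rates_per_100py[event]


def _set_param(bundle: ModelParameters, event: str, arm: str, value: float) -> None:
    """Point the calibration dial: intercept for the comparator arm,
    treatment coefficient for the intervention arm."""
    model = {"hhf": bundle.hhf, "cv_death": bundle.cv_death,
             "noncv_death": bundle.all_cause_death}[event]
    if arm == "SOC" or event == "noncv_death":
        model.intercept = value
    else:
        model.treatment_coef = value


def _get_param(bundle: ModelParameters, event: str, arm: str) -> float:
    model = {"hhf": bundle.hhf, "cv_death": bundle.cv_death,
             "noncv_death": bundle.all_cause_death}[event]
    if arm == "SOC" or event == "noncv_death":
        return model.intercept
    return model.treatment_coef


def calibrate_rate(bundle: ModelParameters, target_rate_per_100py: float,
                   event: str, arm: str, rel_tol: float = 5e-3,
                   bracket_width: float = 3.0) -> ModelParameters:
    """Root-find one risk-equation coefficient to hit a whole-model rate.

    For comparator-arm targets (and the non-CV adjustment, which has no
    treatment effect) the relevant intercept is adjusted; for the
    intervention arm the treatment coefficient is adjusted.  All other
    parameters are untouched.  The fitted bundle reproduces the target
    within ``rel_tol`` relative tolerance.
    """
    if target_rate_per_100py <= 0:
        raise CalibrationError("target rate must be > 0")
    if event not in ("hhf", "cv_death", "noncv_death"):
        raise CalibrationError(f"unknown calibration event {event!r}")
    b = bundle.copy()
    x0 = _get_param(b, event, arm)

    def objective(x: float) -> float:
        _set_param(b, event, arm, x)
        return modelled_rate(b, event, arm) - target_rate_per_100py

    # AFT intercepts: larger -> longer survival -> lower rate (decreasing);
    # log-rate intercepts/coefs: increasing.  brentq handles either sign.
    lo, hi = x0 - bracket_width, x0 + bracket_width
    f_lo, f_hi = objective(lo), objective(hi)
    for _ in range(6):
        if f_lo * f_hi <= 0:
            break
        lo -= bracket_width
        hi += bracket_width
        f_lo, f_hi = objective(lo), objective(hi)
    else:
        raise CalibrationError(
            f"no sign change for {event}/{arm} in bracket [{lo:.2f}, {hi:.2f}]"
            f" (f(lo)={f_lo:.4f}, f(hi)={f_hi:.4f})"
        )
    root = optimize.brentq(objective, lo, hi, xtol=1e-6,
                           rtol=1e-10, maxiter=200)
    _set_param(b, event, arm, root)
    achieved = modelled_rate(b, event, arm)
    if abs(achieved - target_rate_per_100py) / target_rate_per_100py > rel_tol:
        raise CalibrationError(
            f"{event}/{arm}: achieved {achieved:.4f} vs target "
            f"{target_rate_per_100py:.4f} outside tolerance"
        )
    return b


def calibrate_treatment_duration(bundle: ModelParameters, target_years: float,
                                 rel_tol: float = 5e-3) -> ModelParameters:
    """Root-find the discontinuation location so mean years on treatment
    matches the target."""
    if bundle.discontinuation is None:
        raise CalibrationError("bundle has no discontinuation process")
    b = bundle.copy()

    def objective(mu: float) -> float:
        b.discontinuation.intercept = mu
        trace = engine.run_cohort(b, "EPG_SOC")
        return engine.mean_time_on_treatment(trace, b) - target_years

    x0 = b.discontinuation.intercept
    lo, hi = x0 - 3.0, x0 + 3.0
    f_lo, f_hi = objective(lo), objective(hi)
    for _ in range(6):
        if f_lo * f_hi <= 0:
            break
        lo -= 3.0
        hi += 3.0
        f_lo, f_hi = objective(lo), objective(hi)
    else:
        raise CalibrationError(
            f"mean-duration target {target_years} not bracketed in "
            f"intercept range [{lo}, {hi}]"
        )
    root = optimize.brentq(objective, lo, hi, xtol=1e-6, rtol=1e-10)
    b.discontinuation.intercept = root
    trace = engine.run_cohort(b, "EPG_SOC")
    achieved = engine.mean_time_on_treatment(trace, b)
    if abs(achieved - target_years) / target_years > rel_tol:
        raise CalibrationError(
            f"mean duration {achieved:.3f} y vs target {target_years} y"
        )
    return b


def calibration_errors(bundle: ModelParameters,
                       spec: SyntheticSpec) -> dict[str, float]:
    """Relative error of each calibration target on the current bundle."""
    trace = engine.run_cohort(bundle, "EPG_SOC")
    t = spec
    errs = {
        "soc_cv": modelled_rate(bundle, "cv_death", "SOC")
        / t.target_soc_cv_death_rate - 1.0,
        "epg_cv": modelled_rate(bundle, "cv_death", "EPG_SOC")
        / t.target_epg_cv_death_rate - 1.0,
        "soc_noncv": modelled_rate(bundle, "noncv_death", "SOC")
        / t.target_soc_noncv_rate - 1.0,
        "soc_hhf": modelled_rate(bundle, "hhf", "SOC")
        / t.target_soc_hhf_rate - 1.0,
        "epg_hhf": modelled_rate(bundle, "hhf", "EPG_SOC")
        / t.target_epg_hhf_rate - 1.0,
        "years_on_trt": engine.mean_time_on_treatment(trace, bundle)
        / t.target_mean_years_on_treatment - 1.0,
    }
    return errs


def calibrated_bundle(spec: SyntheticSpec | None = None,
                      rel_tol: float = 2e-3,
                      max_passes: int = 6) -> ModelParameters:
    """Generate and fully calibrate a bundle to the spec's rate targets.

    One pass calibrates, in order: CV death (comparator intercept, then
    intervention coefficient), the non-CV adjustment (all-cause
    intercept), hHF (intercept then coefficient), then treatment duration
    — survival first because downstream person-years depend on it.  The
    steps interact (mortality changes person-years; discontinuation
    changes the intervention arm's exposure), so passes repeat until every
    target is met jointly within ``rel_tol``.
    """
    spec = spec or SyntheticSpec()
    b = generate_bundle(spec)
    for _ in range(max_passes):
        b = calibrate_rate(b, spec.target_soc_cv_death_rate, "cv_death", "SOC")
        b = calibrate_rate(b, spec.target_epg_cv_death_rate, "cv_death",
                           "EPG_SOC")
        b = calibrate_rate(b, spec.target_soc_noncv_rate, "noncv_death", "SOC")
        b = calibrate_rate(b, spec.target_soc_hhf_rate, "hhf", "SOC")
        b = calibrate_rate(b, spec.target_epg_hhf_rate, "hhf", "EPG_SOC")
        b = calibrate_treatment_duration(
            b, spec.target_mean_years_on_treatment)
        errs = calibration_errors(b, spec)
        if max(abs(v) for v in errs.values()) < rel_tol:
            break
    else:
        raise CalibrationError(
            f"joint calibration did not converge in {max_passes} passes: "
            f"{ {k: round(v, 4) for k, v in errs.items()} }"
        )
    return require_valid(b)


# ---------------------------------------------------------------------------
# Survival-family swaps (scenario analyses)
# ---------------------------------------------------------------------------

_FAMILY_ANCILLARY: dict[str, dict[str, float]] = {
    "exponential": {},
    "weibull": {"shape": 1.1},
    "lognormal": {"sigma": 1.2},
    "loglogistic": {"shape": 1.3},
    "gompertz": {"gamma": 0.004},
    "gengamma": {"sigma": 0.9, "q": 1.2},
}

_FAMILY_INTERCEPT_GUESS = {
    # AFT families: log median-ish time; PH families: log monthly hazard
    "exponential": -5.5, "gompertz": -6.0, "weibull": 4.5,
    "lognormal": 4.5, "loglogistic": 4.5, "gengamma": 4.5,
}


def refit_survival_family(bundle: ModelParameters, process: str,
                          family: str) -> ModelParameters:
    """Swap a time-to-event process onto another parametric family.

    The new family keeps the old state coefficients (rescaled only in
    sign-neutral AFT/PH sense is not attempted — they are reused as-is)
    and its intercept / treatment coefficient are re-calibrated so the
    whole-model per-100-PY rates (or mean treatment duration) match the
    base bundle, i.e. the families differ in tail behaviour, not in the
    modelled horizon-average event rates.
    """
    if family not in _FAMILY_ANCILLARY:
        raise ValueError(f"unsupported survival family {family!r}")
    base = bundle.copy()
    if process == "mortality":
        soc_cv = modelled_rate(base, "cv_death", "SOC")
        epg_cv = modelled_rate(base, "cv_death", "EPG_SOC")
        soc_ncv = modelled_rate(base, "noncv_death", "SOC")
        b = base.copy()
        # worse states carry more risk: positive log-hazard coefficients in
        # PH families, negative log-time coefficients in AFT families
        ph = family in ("exponential", "gompertz")
        for attr in ("cv_death", "all_cause_death"):
            old = getattr(b, attr)
            setattr(b, attr, SurvivalSpec(
                family=family,
                intercept=_FAMILY_INTERCEPT_GUESS[family],
                treatment_coef=0.0,
                state_coefs={k: (abs(v) if ph else -abs(v))
                             for k, v in old.state_coefs.items()},
                ancillary=dict(_FAMILY_ANCILLARY[family]),
            ))
        b = calibrate_rate(b, soc_cv, "cv_death", "SOC")
        b = calibrate_rate(b, epg_cv, "cv_death", "EPG_SOC")
        b = calibrate_rate(b, soc_ncv, "noncv_death", "SOC")
        return b
    if process == "discontinuation":
        trace = engine.run_cohort(base, "EPG_SOC")
        target = engine.mean_time_on_treatment(trace, base)
        b = base.copy()
        old = b.discontinuation
        sign_flip = family in ("exponential", "gompertz")
        b.discontinuation = SurvivalSpec(
            family=family,
            intercept=_FAMILY_INTERCEPT_GUESS[family],
            treatment_coef=0.0,
            state_coefs={k: (abs(v) if sign_flip else -abs(v))
                         for k, v in old.state_coefs.items()},
            ancillary=dict(_FAMILY_ANCILLARY[family]),
        )
        return calibrate_treatment_duration(b, target)
    raise ValueError(f"unknown process {process!r}")
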