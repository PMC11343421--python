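"""Parametric survival extrapolation and life-table blending.

Six time-to-event families are supported.  Accelerated-failure-time (AFT)
families (weibull, lognormal, loglogistic, generalised gamma) take the
covariate linear predictor as the log-time location; proportional-hazards
(PH) families (exponential, gompertz) take it as the log hazard.  This
matches the conventions of common survival-regression software so fitted
coefficients can be transcribed directly.

Time is measured in months since model entry.  Per-cycle conditional event
probabilities use the piecewise-constant covariate approximation: the
alive-state indicator at the start of a cycle selects the hazard for the
whole cycle.

Non-CV background mortality blends the trial-based risk equations with a
general-population life table: each cycle the larger of the two non-CV
probabilities is used, so modelled patients are never healthier than the
general population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .parameters import LifeTable, SurvivalSpec, REFERENCE_STATE

log = logging.getLogger(__name__)


class DegenerateSupportError(ValueError):
    """Survival already exhausted at the requested conditioning time."""


@dataclass
class CyclicHazardContext:
    """Covariate and timing context for one cycle of one cohort stratum."""

    elapsed_time: float  # months since model entry
    cycle_length: float = 1.0
    treatment: int = 0
    state: str = REFERENCE_STATE
    current_age: float | None = None


# ---------------------------------------------------------------------------
# Survival functions
# ---------------------------------------------------------------------------


def _gengamma_survival(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    """Generalised gamma survival, Prentice (mu, sigma, Q) parameterisation.

    Q = 1 recovers a Weibull with shape 1/sigma and scale exp(mu); Q -> 0
    recovers the lognormal(mu, sigma).
    """
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    if abs(q) < 1e-8:
        z = (np.log(t[pos]) - mu) / sigma
        out[pos] = stats.norm.sf(z)
        return out
    w = (np.log(t[pos]) - mu) / sigma
    a = q ** -2
    u = a * np.exp(q * w)
    if q > 0:
        out[pos] = special.gammaincc(a, u)
    else:
        out[pos] = special.gammainc(a, u)
    return out


def survival_probability(
    spec: SurvivalSpec,
    t: float | np.ndarray,
    treatment: int = 0,
    state: str | None = None,
) -> float | np.ndarray:
    """S(t) under the spec's family and the given covariate values.

    Vectorised over ``t`` (months).  S(0) = 1 and S is non-increasing for
    every supported family.
    """
    state = state if state is not None else spec.reference_state
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    lp = spec.linear_predictor(treatment, state)
    fam = spec.family

    if fam == "exponential":
        s = np.exp(-np.exp(lp) * t)
    elif fam == "gompertz":
        gamma = spec.ancillary.get("gamma", 0.0)
        if abs(gamma) < 1e-12:
            s = np.exp(-np.exp(lp) * t)
        else:
            s = np.exp(-np.exp(lp) / gamma * (np.exp(gamma * t) - 1.0))
    elif fam == "weibull":
        shape = spec.ancillary["shape"]
        s = np.exp(-((t / np.exp(lp)) ** shape))
    elif fam == "lognormal":
        sigma = spec.ancillary["sigma"]
        s = np.ones_like(t)
        pos = t > 0
        s[pos] = stats.norm.sf((np.log(t[pos]) - lp) / sigma)
    elif fam == "loglogistic":
        shape = spec.ancillary["shape"]
        s = 1.0 / (1.0 + (t / np.exp(lp)) ** shape)
    elif fam == "gengamma":
        s = _gengamma_survival(t, lp, spec.ancillary["sigma"],
                               spec.ancillary["q"])
    else:
        raise ValueError(f"unsupported survival family: {fam!r}")
    return float(s[0]) if scalar else s


def cycle_event_probability(spec: SurvivalSpec, ctx: CyclicHazardContext) -> float:
    """Conditional probability of the event within the next cycle.

    1 - S(t + cycle) / S(t) with the context's covariates held fixed over
    the cycle.
    """
    s = survival_probability(
        spec, np.array([ctx.elapsed_time, ctx.elapsed_time + ctx.cycle_length]),
        treatment=ctx.treatment, state=ctx.state,
    )
    if s[0] <= 0.0:
        raise DegenerateSupportError(
            f"S({ctx.elapsed_time}) = 0 for family {spec.family!r}"
        )
    return float(min(1.0, max(0.0, 1.0 - s[1] / s[0])))


def cycle_probability_grid(
    spec: SurvivalSpec,
    n_cycles: int,
    cycle_length: float,
    treatment: int,
    state: str,
) -> np.ndarray:
    """Per-cycle conditional event probabilities for cycles 0..n_cycles-1.

    Vectorised version of :func:`cycle_event_probability` used by the
    cohort engine.  Where the survival function has numerically vanished
    the conditional probability is set to 1.
    """
    edges = np.arange(n_cycles + 1, dtype=float) * cycle_length
    s = survival_probability(spec, edges, treatment=treatment, state=state)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 1.0 - np.where(s[:-1] > 0.0, s[1:] / s[:-1], 0.0)
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Background (life-table) mortality
# ---------------------------------------------------------------------------


def noncv_lifetable_probability(
    lt: LifeTable, age: float, sex_mix: dict[str, float] | None = None
) -> float:
    """Monthly non-CV death probability from the general-population table.

    The sex-mix-weighted annual non-CV probability is the all-cause
    probability times (1 - CV share of deaths); it is converted to a
    monthly probability via 1 - (1 - p)^(1/12).
    """
    mix = sex_mix if sex_mix is not None else lt.sex_mix
    age_i = int(math.floor(age))
    annual = 0.0
    for sex, w in mix.items():
        qx, cv_share = lt.annual_row(age_i, sex)
        annual += w * qx * (1.0 - cv_share)
    return 1.0 - (1.0 - annual) ** (1.0 / 12.0)


def trial_noncv_probability(
    all_cause_spec: SurvivalSpec,
    cv_spec: SurvivalSpec,
    ctx: CyclicHazardContext,
) -> float:
    """Trial-based per-cycle non-CV probability: max(0, p_all-cause - p_CV)."""
    p_ac = cycle_event_probability(all_cause_spec, ctx)
    p_cv = cycle_event_probability(cv_spec, ctx)
    if p_cv > p_ac:
        log.warning(
            "CV-death probability (%.4g) exceeds all-cause (%.4g) at t=%.1f; "
            "trial-based non-CV probability floored at 0", p_cv, p_ac,
            ctx.elapsed_time,
        )
        return 0.0
    return p_ac - p_cv


def blended_noncv_probability(trial_based: float, lifetable_based: float) -> float:
    """Use whichever non-CV probability is larger (general-population floor)."""
    return max(trial_based, lifetable_based)


# ---------------------------------------------------------------------------
# Hazard-ratio handling
# ---------------------------------------------------------------------------


def treatment_coef_for_hazard_ratio(spec: SurvivalSpec, hr: float) -> float:
    """Treatment coefficient equivalent to a proportional-hazards ratio.

    Exact for the PH families and for the Weibull AFT (where a time ratio
    exp(b) corresponds to HR = exp(-b * shape)); HR = 1 maps to a zero
    coefficient for every family.  Other AFT families have no exact PH
    representation and are rejected for hr != 1.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if hr == 1.0:
        return 0.0
    if spec.convention == "ph":
        return math.log(hr)
    if spec.family == "weibull":
        return -math.log(hr) / spec.ancillary["shape"]
    if spec.family == "gengamma" and abs(spec.ancillary.get("q", 0.0) - 1.0) < 1e-12:
        return -math.log(hr) * spec.ancillary["sigma"]
    raise ValueError(
        f"no exact proportional-hazards mapping for family {spec.family!r}"
    )
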