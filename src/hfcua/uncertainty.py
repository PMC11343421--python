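"""One-way deterministic, probabilistic, scenario and subgroup analyses.

Parameters are addressed by dotted paths into the bundle (e.g.
``costs.monthly_drug_cost.EPG_SOC`` or ``utilities.state_utility.Q1``).
Two virtual paths re-express treatment effects on their natural scale:
``treatment.rr_hhf`` (hospitalisation rate ratio) and
``treatment.hr_cv_death`` (CV-death hazard ratio), which are converted to
the appropriate model coefficients when set.

Every analysis works on deep copies: the base bundle is never modified.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics, engine, synthetic
from .parameters import (ALIVE_STATES, ARMS, PERIODS, ModelParameters,
                         validate_parameters)
from .survival import treatment_coef_for_hazard_ratio

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter paths
# ---------------------------------------------------------------------------


def _resolve(bundle: ModelParameters, path: str):
    parts = path.split(".")
    obj = bundle
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj, parts[-1]


def get_by_path(bundle: ModelParameters, path: str) -> float:
    if path == "treatment.rr_hhf":
        return math.exp(bundle.hhf.treatment_coef)
    if path == "treatment.hr_cv_death":
        spec = bundle.cv_death
        if spec.family == "weibull":
            return math.exp(-spec.treatment_coef * spec.ancillary["shape"])
        return math.exp(spec.treatment_coef)
    obj, leaf = _resolve(bundle, path)
    return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)


def set_by_path(bundle: ModelParameters, path: str, value: float) -> None:
    """Set a (possibly virtual) parameter in place."""
    if path == "treatment.rr_hhf":
        bundle.hhf.treatment_coef = math.log(value)
        return
    if path == "treatment.hr_cv_death":
        bundle.cv_death.treatment_coef = treatment_coef_for_hazard_ratio(
            bundle.cv_death, value)
        return
    obj, leaf = _resolve(bundle, path)
    if isinstance(obj, dict):
        if leaf not in obj:
            raise KeyError(f"unknown parameter path: {path}")
        obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise AttributeError(f"unknown parameter path: {path}")
        setattr(obj, leaf, value)


def with_overrides(bundle: ModelParameters,
                   overrides: dict[str, float]) -> ModelParameters:
    b = bundle.copy()
    for path, value in overrides.items():
        set_by_path(b, path, value)
    return b


def deterministic_icer(bundle: ModelParameters) -> economics.IncrementalResult:
    """Run both arms and return the incremental result."""
    a = engine.run_arm(bundle, "EPG_SOC")
    b = engine.run_arm(bundle, "SOC")
    return economics.incremental(a, b)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class DsaSpec:
    """One tornado bar: a parameter path with its low/high values."""

    path: str
    low: float
    high: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(
                f"{self.path}: low {self.low} > high {self.high}")


def default_dsa_specs(bundle: ModelParameters) -> list[DsaSpec]:
    """Plausible-range specs: printed CI bounds for treatment effects,
    +/-20% for costs, +/-10% for utilities."""
    specs: list[DsaSpec] = []
    lo, hi = bundle.treatment_effect.hr_hhf_dsa
    specs.append(DsaSpec("treatment.rr_hhf", lo, hi, "95% CI"))
    specs.append(DsaSpec("treatment.hr_cv_death",
                         get_by_path(bundle, "treatment.hr_cv_death"), 1.0,
                         "effect removed at high"))
    for path in ("costs.monthly_drug_cost.EPG_SOC", "costs.hhf_cost",
                 "costs.cv_death_cost", "costs.monthly_disease_mgmt_cost"):
        v = get_by_path(bundle, path)
        specs.append(DsaSpec(path, 0.8 * v, 1.2 * v, "+/-20%"))
    # utility ranges: +/-10% but clipped so the quartile ordering survives
    us = bundle.utilities.state_utility
    for i, s in enumerate(ALIVE_STATES):
        v = us[s]
        lo_bound = us[ALIVE_STATES[i - 1]] + 1e-6 if i > 0 else 0.0
        hi_bound = (us[ALIVE_STATES[i + 1]] - 1e-6
                    if i < len(ALIVE_STATES) - 1 else 1.0)
        specs.append(DsaSpec(f"utilities.state_utility.{s}",
                             max(0.9 * v, lo_bound), min(1.1 * v, hi_bound),
                             "+/-10%, order-clipped"))
    v = bundle.utilities.hhf_disutility
    specs.append(DsaSpec("utilities.hhf_disutility", 1.2 * v, 0.8 * v,
                         "+/-20% (negative)"))
    return specs


def run_dsa(base: ModelParameters, specs: list[DsaSpec],
            base_result: economics.IncrementalResult | None = None
            ) -> pd.DataFrame:
    """Tornado table: ICER at each spec's low and high, all else at base.

    Rows are sorted by bar width (|ICER_high - ICER_low|) descending;
    rows whose bar crosses the cost-effectiveness threshold are flagged.
    A spec that produces an invalid bundle is marked failed and the run
    continues.
    """
    base_result = base_result or deterministic_icer(base)
    cet = base.economics.cet
    rows = []
    for spec in specs:
        row = {"parameter": spec.path, "note": spec.note,
               "low": spec.low, "high": spec.high,
               "icer_low": np.nan, "icer_high": np.nan,
               "tag_low": "", "tag_high": "", "failed": False}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            try:
                b = with_overrides(base, {spec.path: value})
                problems = validate_parameters(b)
                if problems:
                    raise ValueError("; ".join(problems))
                res = deterministic_icer(b)
            except Exception as exc:  # keep the tornado going
                log.warning("DSA %s at %s failed: %s", spec.path, bound, exc)
                row["failed"] = True
                continue
            row[f"tag_{bound}"] = res.tag
            if res.icer_per_qaly is not None:
                row[f"icer_{bound}"] = res.icer_per_qaly
        rows.append(row)
    df = pd.DataFrame(rows)
    df["spread"] = (df["icer_high"] - df["icer_low"]).abs()
    df["crosses_cet"] = (
        (df[["icer_low", "icer_high"]].min(axis=1) < cet)
        & (df[["icer_low", "icer_high"]].max(axis=1) > cet)
    )
    df["base_icer"] = base_result.icer_per_qaly
    return df.sort_values("spread", ascending=False,
                          na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaDistributionSpec:
    """One sampled parameter: path, family, and (mean, sd) hyperparameters.

    Families: beta (moment-matched, for utilities/probabilities), gamma
    (costs and other positives), lognormal (hazard/rate ratios; sd is the
    log-scale sigma), normal, and dirichlet_row for transition-matrix rows
    (path ``transitions.<arm>.<period>``; ``concentration`` scales the
    base row).
    """

    path: str
    family: str
    mean: float = math.nan
    sd: float = math.nan
    concentration: float = 100.0
    group: str = ""   # draws sharing a group are redrawn together


def default_psa_specs(bundle: ModelParameters) -> list[PsaDistributionSpec]:
    specs: list[PsaDistributionSpec] = []
    for s in ALIVE_STATES:
        m = bundle.utilities.state_utility[s]
        specs.append(PsaDistributionSpec(
            f"utilities.state_utility.{s}", "beta", m, 0.10 * m,
            group="state_utilities"))
    for path in ("costs.monthly_drug_cost.EPG_SOC",
                 "costs.monthly_drug_cost.SOC", "costs.hhf_cost",
                 "costs.cv_death_cost", "costs.monthly_disease_mgmt_cost"):
        m = get_by_path(bundle, path)
        specs.append(PsaDistributionSpec(path, "gamma", m, 0.20 * m))
    for name, ev in bundle.adverse_events.active().items():
        specs.append(PsaDistributionSpec(
            f"adverse_events.events.{name}.unit_cost", "gamma",
            ev.unit_cost, 0.20 * ev.unit_cost))
        for arm, key in (("EPG_SOC", "EPG_SOC"), ("SOC", "SOC")):
            m = ev.monthly_rate[key]
            specs.append(PsaDistributionSpec(
                f"adverse_events.events.{name}.monthly_rate.{key}",
                "beta", m, 0.10 * m))
    # treatment effects on the ratio scale; hHF sigma from the printed
    # composite CI 0.69-0.90, CV-death sigma a wider assumption
    specs.append(PsaDistributionSpec(
        "treatment.rr_hhf", "lognormal",
        get_by_path(bundle, "treatment.rr_hhf"),
        (math.log(0.90) - math.log(0.69)) / (2 * 1.959964)))
    specs.append(PsaDistributionSpec(
        "treatment.hr_cv_death", "lognormal",
        get_by_path(bundle, "treatment.hr_cv_death"), 0.09))
    m = abs(bundle.utilities.hhf_disutility)
    specs.append(PsaDistributionSpec(
        "utilities.hhf_disutility", "gamma", m, 0.10 * m, group="negate"))
    for arm in ARMS:
        for period in PERIODS:
            specs.append(PsaDistributionSpec(
                f"transitions.{arm}.{period}", "dirichlet_row",
                concentration=100.0))
    return specs


def _draw(spec: PsaDistributionSpec, rng: np.random.Generator) -> float:
    m, sd = spec.mean, spec.sd
    if sd == 0.0:
        return m
    if spec.family == "beta":
        var = sd * sd
        common = m * (1.0 - m) / var - 1.0
        if common <= 0:
            raise ValueError(f"{spec.path}: beta sd too large for mean")
        return float(rng.beta(m * common, (1.0 - m) * common))
    if spec.family == "gamma":
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return float(rng.gamma(shape, scale))
    if spec.family == "lognormal":
        return float(rng.lognormal(math.log(m), sd))
    if spec.family == "normal":
        return float(rng.normal(m, sd))
    raise ValueError(f"unsupported PSA family {spec.family!r}")


def sample_bundle(base: ModelParameters, dists: list[PsaDistributionSpec],
                  rng: np.random.Generator,
                  max_retries: int = 100) -> ModelParameters:
    """Draw one joint parameter set.  Invalid draws (e.g. non-monotone
    utilities) are redrawn, with a hard error past ``max_retries``."""
    b = base.copy()
    utility_specs = [d for d in dists if d.group == "state_utilities"]
    other = [d for d in dists if d.group != "state_utilities"]

    for spec in other:
        if spec.family == "dirichlet_row":
            _, arm, period = spec.path.split(".")
            base_m = base.transitions.matrices[(arm, period)]
            new = np.vstack([
                rng.dirichlet(spec.concentration * np.maximum(row, 1e-9))
                for row in base_m
            ])
            b.transitions.matrices[(arm, period)] = new
            continue
        value = _draw(spec, rng)
        if spec.group == "negate":
            value = -value
        set_by_path(b, spec.path, value)

    if utility_specs:
        order = [s.path.rsplit(".", 1)[1] for s in utility_specs]
        for attempt in range(max_retries + 1):
            draws = {st: _draw(sp, rng)
                     for st, sp in zip(order, utility_specs)}
            vals = [draws[s] for s in ALIVE_STATES if s in draws]
            if all(x < y for x, y in zip(vals[:-1], vals[1:])):
                if attempt:
                    log.debug("utility block redrawn %d time(s)", attempt)
                for sp, st in zip(utility_specs, order):
                    set_by_path(b, sp.path, draws[st])
                break
        else:
            raise RuntimeError(
                "utility draws failed monotonicity after "
                f"{max_retries} retries")
    return b


def run_psa(base: ModelParameters,
            dists: list[PsaDistributionSpec] | None = None,
            n: int = 1000, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo PSA: jointly sample all parameters, run both arms.

    Returns the per-iteration sample table and a manifest recording the
    seed and the distribution specs.  Bitwise reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dists is None:
        dists = default_psa_specs(base)
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n):
        b = sample_bundle(base, dists, rng)
        sa = engine.run_arm(b, "EPG_SOC")
        sb = engine.run_arm(b, "SOC")
        rows.append({
            "iteration": it,
            "cost_epg_soc": sa.discounted.cost_total,
            "ly_epg_soc": sa.discounted.ly_total,
            "qaly_epg_soc": sa.discounted.qaly_total,
            "cost_soc": sb.discounted.cost_total,
            "ly_soc": sb.discounted.ly_total,
            "qaly_soc": sb.discounted.qaly_total,
        })
    samples = pd.DataFrame(rows, columns=economics.PSA_COLUMNS)
    manifest = {
        "seed": seed,
        "n_iterations": n,
        "distributions": [
            {"path": d.path, "family": d.family, "mean": d.mean, "sd": d.sd,
             "concentration": d.concentration}
            for d in dists
        ],
    }
    return samples, manifest


# ---------------------------------------------------------------------------
# Scenario / subgroup analyses
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Named overrides of economic settings and model structure."""

    name: str
    param_overrides: dict[str, float] = field(default_factory=dict)
    horizon: int | str | None = None
    discount_rate: float | None = None
    starting_age: float | None = None
    mortality_family: str | None = None
    discontinuation_family: str | None = None
    no_discontinuation: bool = False
    include_ketoacidosis: bool = False
    subgroup: str | None = None

    def apply(self, base: ModelParameters) -> ModelParameters:
        b = base.copy()
        if self.horizon is not None:
            b.economics.horizon = self.horizon
        if self.discount_rate is not None:
            b.economics.annual_discount_rate_cost = self.discount_rate
            b.economics.annual_discount_rate_benefit = self.discount_rate
        if self.starting_age is not None:
            b.economics.starting_age = self.starting_age
        if self.no_discontinuation:
            b.discontinuation = None
        if self.include_ketoacidosis:
            b.adverse_events.include_ketoacidosis = True
        if self.subgroup is not None:
            hrs = base.treatment_effect.subgroups[self.subgroup]
            set_by_path(b, "treatment.hr_cv_death", hrs["hr_cv_death"])
            set_by_path(b, "treatment.rr_hhf", hrs["rr_hhf"])
        if self.mortality_family is not None:
            b = synthetic.refit_survival_family(b, "mortality",
                                                self.mortality_family)
        if self.discontinuation_family is not None:
            b = synthetic.refit_survival_family(b, "discontinuation",
                                                self.discontinuation_family)
        for path, value in self.param_overrides.items():
            set_by_path(b, path, value)
        return b


def default_scenarios(base: ModelParameters) -> list[ScenarioSpec]:
    """The published scenario grid (procurement-price scenario excluded:
    those prices are not public)."""
    scen = [
        ScenarioSpec("starting_age_71.9", starting_age=71.9),
        ScenarioSpec("horizon_5y", horizon=60),
        ScenarioSpec("horizon_10y", horizon=120),
        ScenarioSpec("discount_0pct", discount_rate=0.0),
        ScenarioSpec("discount_5pct", discount_rate=0.05),
    ]
    for fam in ("lognormal", "loglogistic", "exponential", "gengamma",
                "gompertz"):
        scen.append(ScenarioSpec(f"mortality_{fam}", mortality_family=fam))
    for fam in ("weibull", "lognormal", "loglogistic", "exponential",
                "gompertz"):
        scen.append(ScenarioSpec(f"discontinuation_{fam}",
                                 discontinuation_family=fam))
    scen.append(ScenarioSpec("ketoacidosis_included",
                             include_ketoacidosis=True))
    scen.append(ScenarioSpec("no_discontinuation", no_discontinuation=True))
    scen.append(ScenarioSpec("no_cv_benefit",
                             param_overrides={"treatment.hr_cv_death": 1.0}))
    scen.append(ScenarioSpec("subgroup_t2d", subgroup="t2d"))
    scen.append(ScenarioSpec("subgroup_non_t2d", subgroup="non_t2d"))
    return scen


def run_scenarios(base: ModelParameters,
                  specs: list[ScenarioSpec]) -> pd.DataFrame:
    """ICER per scenario with the percent change from the base case.

    The table always starts with the base-case row (0% change); a scenario
    that fails to produce a valid bundle is marked failed and skipped.
    """
    base_res = deterministic_icer(base)
    base_icer = base_res.icer_per_qaly
    rows = [{"scenario": "base_case", "icer_per_qaly": base_icer,
             "delta_cost": base_res.delta_cost,
             "delta_qaly": base_res.delta_qaly,
             "pct_change": 0.0, "tag": base_res.tag, "failed": False}]
    for spec in specs:
        try:
            b = spec.apply(base)
            res = deterministic_icer(b)
        except Exception as exc:
            log.warning("scenario %s failed: %s", spec.name, exc)
            rows.append({"scenario": spec.name, "icer_per_qaly": np.nan,
                         "delta_cost": np.nan, "delta_qaly": np.nan,
                         "pct_change": np.nan, "tag": "", "failed": True})
            continue
        icer = res.icer_per_qaly
        pct = (100.0 * (icer / base_icer - 1.0)
               if (icer is not None and base_icer) else np.nan)
        rows.append({"scenario": spec.name,
                     "icer_per_qaly": icer if icer is not None else np.nan,
                     "delta_cost": res.delta_cost,
                     "delta_qaly": res.delta_qaly,
                     "pct_change": pct, "tag": res.tag, "failed": False})
    return pd.DataFrame(rows)
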