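"""Parameter bundle for the heart-failure cost-utility Markov model.

The model follows a cohort of chronic heart-failure patients (ejection
fraction > 40%) through four alive health states defined by Kansas City
Cardiomyopathy Questionnaire clinical summary score (KCCQ-CSS) quartiles,
plus cardiovascular (CV) and non-CV death.  Everything the engine consumes
— transition matrices, parametric risk equations, event rates, costs,
utilities, the general-population life table and economic settings — is
collected in a single :class:`ModelParameters` bundle that can be read
from, and written back to, a small human-editable configuration directory
(YAML + CSV).
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Model vocabulary
# ---------------------------------------------------------------------------

ALIVE_STATES: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")
DEAD_STATES: tuple[str, ...] = ("DEAD_CV", "DEAD_NONCV")
ARMS: tuple[str, ...] = ("EPG_SOC", "SOC")
PERIODS: tuple[str, ...] = ("m1_3", "m4_8", "m9plus")
#: cycle indices (0-based) at which the transition-matrix period changes:
#: cycles 0-2 are months 1-3, cycles 3-7 months 4-8, cycles 8+ months 9+.
PERIOD_BREAKS: tuple[int, int] = (3, 8)

#: KCCQ-CSS quartile boundaries from the trial population distribution.
KCCQ_BOUNDS: tuple[float, ...] = (0.0, 55.73, 73.96, 88.02, 100.0)

AE_NAMES: tuple[str, ...] = (
    "urinary_tract_infection",
    "genital_infection",
    "acute_renal_failure",
    "hepatic_injury",
    "volume_depletion",
    "hypotension",
    "hypoglycaemia",
    "bone_fracture",
)
KETOACIDOSIS = "ketoacidosis"

#: supported parametric time-to-event families and the convention in which
#: their covariate linear predictor enters (see survival module).
SURVIVAL_FAMILIES: dict[str, str] = {
    "exponential": "ph",
    "gompertz": "ph",
    "weibull": "aft",
    "lognormal": "aft",
    "loglogistic": "aft",
    "gengamma": "aft",
}

#: reference alive state for covariate coding (best health).
REFERENCE_STATE = "Q4"


class ConfigurationError(ValueError):
    """Raised when a parameter source cannot be parsed into a valid bundle."""


class DimensionError(ConfigurationError):
    """Raised when a tabular input has the wrong shape."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HealthStateDefinition:
    """One alive health state: a KCCQ-CSS quartile band."""

    state_id: str
    kccq_lower: float
    kccq_upper: float


def default_health_states() -> tuple[HealthStateDefinition, ...]:
    return tuple(
        HealthStateDefinition(s, KCCQ_BOUNDS[i], KCCQ_BOUNDS[i + 1])
        for i, s in enumerate(ALIVE_STATES)
    )


@dataclass
class TransitionSchedule:
    """Three-period, treatment-specific monthly transition matrices.

    ``matrices[(arm, period)]`` is a 4x4 row-stochastic matrix over the
    alive states, conditional on surviving the cycle.  The months-9+
    matrices apply unchanged until the end of the horizon.
    """

    matrices: dict[tuple[str, str], np.ndarray]
    period_breaks: tuple[int, int] = PERIOD_BREAKS

    def period_for_cycle(self, cycle: int) -> str:
        if cycle < self.period_breaks[0]:
            return "m1_3"
        if cycle < self.period_breaks[1]:
            return "m4_8"
        return "m9plus"

    def matrix(self, arm: str, cycle: int) -> np.ndarray:
        return self.matrices[(arm, self.period_for_cycle(cycle))]


@dataclass
class SurvivalSpec:
    """A parametric time-to-event process with covariate effects.

    ``intercept`` plus the covariate terms form the linear predictor:
    the log-location (log time scale) for AFT families
    (weibull/lognormal/loglogistic/gengamma) and the log hazard for PH
    families (exponential/gompertz).  ``state_coefs`` code the time-varying
    alive state relative to the declared reference state.  Time is in
    months since model entry.
    """

    family: str
    intercept: float
    treatment_coef: float = 0.0
    state_coefs: dict[str, float] = field(default_factory=dict)
    ancillary: dict[str, float] = field(default_factory=dict)
    reference_state: str = REFERENCE_STATE
    time_unit: str = "months"

    @property
    def convention(self) -> str:
        try:
            return SURVIVAL_FAMILIES[self.family]
        except KeyError:
            raise ConfigurationError(f"unsupported survival family: {self.family!r}")

    def linear_predictor(self, treatment: int, state: str) -> float:
        lp = self.intercept + self.treatment_coef * treatment
        if state != self.reference_state:
            lp += self.state_coefs.get(state, 0.0)
        return lp


@dataclass
class EventRateModel:
    """Log-linear (Poisson) model for a recurrent event's monthly rate."""

    intercept: float
    treatment_coef: float = 0.0
    state_coefs: dict[str, float] = field(default_factory=dict)
    reference_state: str = REFERENCE_STATE

    def monthly_rate(self, treatment: int, state: str) -> float:
        lp = self.intercept + self.treatment_coef * treatment
        if state != self.reference_state:
            lp += self.state_coefs.get(state, 0.0)
        return math.exp(lp)


@dataclass
class AdverseEvent:
    """One treatment-emergent adverse event type."""

    name: str
    monthly_rate: dict[str, float]  # per arm
    disutility: float
    unit_cost: float
    disutility_duration_months: float = 1.0


@dataclass
class AdverseEventProfile:
    events: dict[str, AdverseEvent]
    include_ketoacidosis: bool = False

    def active(self) -> dict[str, AdverseEvent]:
        out = {}
        for name, ev in self.events.items():
            if name == KETOACIDOSIS and not self.include_ketoacidosis:
                continue
            out[name] = ev
        return out


@dataclass
class CostSet:
    """Direct medical costs, 2022 Malaysian ringgit (RM)."""

    monthly_drug_cost: dict[str, float]  # per arm; off-treatment uses SOC
    hhf_cost: float
    cv_death_cost: float
    noncv_death_cost: float
    monthly_disease_mgmt_cost: float
    currency_year: int = 2022


@dataclass
class UtilityModel:
    """Health-state utilities and one-off event utility decrements."""

    state_utility: dict[str, float]
    hhf_disutility: float = -0.335
    hhf_disutility_duration_months: float = 12.0


@dataclass
class EconomicConfig:
    annual_discount_rate_cost: float = 0.03
    annual_discount_rate_benefit: float = 0.03
    cet: float = 47_439.0
    cycle_length_months: float = 1.0
    horizon: int | str = "lifetime"  # months, or "lifetime"
    starting_age: float = 64.6
    half_cycle_correction: bool = True
    max_age: float = 100.0


@dataclass
class LifeTable:
    """General-population mortality with the CV share of deaths.

    ``table`` has columns age, sex, annual_qx, cv_share; ``sex_mix`` gives
    the male/female composition of the modelled cohort.
    """

    table: pd.DataFrame
    sex_mix: dict[str, float] = field(
        default_factory=lambda: {"male": 0.55, "female": 0.45}
    )

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self._lookup = {
            (int(r.age), str(r.sex)): (float(r.annual_qx), float(r.cv_share))
            for r in self.table.itertuples()
        }

    @property
    def min_age(self) -> int:
        return int(self.table["age"].min())

    @property
    def max_age(self) -> int:
        return int(self.table["age"].max())

    def annual_row(self, age: int, sex: str) -> tuple[float, float]:
        try:
            return self._lookup[(int(age), sex)]
        except KeyError:
            raise KeyError(f"life table has no row for age={age}, sex={sex!r}")


@dataclass
class TreatmentEffect:
    """Treatment-effect handles for sensitivity and subgroup analyses.

    Base-case effects are embedded in the hHF rate model and CV-death
    survival spec; this records the DSA bounds and subgroup hazard-ratio
    overrides used to modify them.
    """

    hr_hhf_dsa: tuple[float, float] = (0.69, 0.83)
    subgroups: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "t2d": {"hr_cv_death": 1.01, "rr_hhf": 0.78},
            "non_t2d": {"hr_cv_death": 0.83, "rr_hhf": 0.77},
        }
    )


@dataclass
class CombineSpec:
    """Phenotype-prevalence weighting for pooling with the HFrEF result."""

    weight_hfref: float = 0.67
    weight_ef40: float = 0.33
    psa_resample_counts: tuple[int, int] = (670, 330)
    psa_total: int = 1000


@dataclass
class ModelParameters:
    """Complete validated input bundle for one modelled population."""

    states: tuple[HealthStateDefinition, ...]
    transitions: TransitionSchedule
    hhf: EventRateModel
    cv_death: SurvivalSpec
    all_cause_death: SurvivalSpec
    discontinuation: SurvivalSpec | None
    adverse_events: AdverseEventProfile
    costs: CostSet
    utilities: UtilityModel
    economics: EconomicConfig
    life_table: LifeTable
    treatment_effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    combine: CombineSpec = field(default_factory=CombineSpec)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_parameters(p: ModelParameters) -> list[str]:
    """Check every type invariant; return one message per violation.

    An empty report means the bundle is valid.  Messages name the field and
    the rule violated.
    """
    report: list[str] = []

    # health states
    if len(p.states) != 4:
        report.append(f"states: expected exactly 4 alive states, got {len(p.states)}")
    else:
        bounds = [p.states[0].kccq_lower] + [s.kccq_upper for s in p.states]
        if not np.allclose(bounds, KCCQ_BOUNDS):
            report.append(f"states: quartile bounds {bounds} != {list(KCCQ_BOUNDS)}")
        for a, b in zip(p.states[:-1], p.states[1:]):
            if not math.isclose(a.kccq_upper, b.kccq_lower):
                report.append(
                    f"states: bands not contiguous at {a.state_id}/{b.state_id}"
                )

    # transition matrices
    for arm in ARMS:
        for period in PERIODS:
            key = (arm, period)
            if key not in p.transitions.matrices:
                report.append(f"transitions[{arm},{period}]: missing matrix")
                continue
            m = np.asarray(p.transitions.matrices[key], dtype=float)
            if m.shape != (4, 4):
                report.append(f"transitions[{arm},{period}]: shape {m.shape} != (4, 4)")
                continue
            if (m < 0).any() or (m > 1).any():
                report.append(f"transitions[{arm},{period}]: entries outside [0, 1]")
            bad = np.abs(m.sum(axis=1) - 1.0) > 1e-9
            for i in np.nonzero(bad)[0]:
                report.append(
                    f"transitions[{arm},{period}] row {ALIVE_STATES[i]}: "
                    f"row sum != 1 (got {m[i].sum():.6f})"
                )

    # survival specs
    for label, spec in (
        ("cv_death", p.cv_death),
        ("all_cause_death", p.all_cause_death),
        ("discontinuation", p.discontinuation),
    ):
        if spec is None:
            continue
        if spec.family not in SURVIVAL_FAMILIES:
            report.append(f"{label}: unsupported family {spec.family!r}")
            continue
        for key in ("shape", "sigma"):
            if key in spec.ancillary and spec.ancillary[key] <= 0:
                report.append(f"{label}: ancillary {key} must be > 0")
        extra = set(spec.state_coefs) - set(ALIVE_STATES)
        if extra:
            report.append(f"{label}: state_coefs for unknown states {sorted(extra)}")
        if spec.reference_state in spec.state_coefs:
            report.append(f"{label}: reference state has an explicit coefficient")

    # event rate model
    extra = set(p.hhf.state_coefs) - set(ALIVE_STATES)
    if extra:
        report.append(f"hhf: state_coefs for unknown states {sorted(extra)}")
    for trt in (0, 1):
        for s in ALIVE_STATES:
            r = p.hhf.monthly_rate(trt, s)
            if not math.isfinite(r) or r < 0:
                report.append(f"hhf: rate not finite/non-negative for {s}, trt={trt}")

    # adverse events
    for name, ev in p.adverse_events.events.items():
        for arm in ARMS:
            if ev.monthly_rate.get(arm, -1.0) < 0:
                report.append(f"adverse_events[{name}]: rate for {arm} missing or < 0")
        if ev.disutility > 0:
            report.append(f"adverse_events[{name}]: disutility must be <= 0")
        if ev.unit_cost < 0:
            report.append(f"adverse_events[{name}]: unit_cost must be >= 0")

    # costs
    for arm in ARMS:
        if p.costs.monthly_drug_cost.get(arm, -1.0) < 0:
            report.append(f"costs.monthly_drug_cost[{arm}]: missing or < 0")
    for fname in ("hhf_cost", "cv_death_cost", "noncv_death_cost",
                  "monthly_disease_mgmt_cost"):
        if getattr(p.costs, fname) < 0:
            report.append(f"costs.{fname}: must be >= 0")

    # utilities
    us = [p.utilities.state_utility.get(s) for s in ALIVE_STATES]
    if any(u is None for u in us):
        report.append("utilities.state_utility: missing a state")
    else:
        if any(not 0.0 <= u <= 1.0 for u in us):
            report.append("utilities.state_utility: values outside [0, 1]")
        if not all(a < b for a, b in zip(us[:-1], us[1:])):
            report.append(
                "utilities.state_utility: monotonicity violated "
                "(must be strictly increasing Q1 -> Q4)"
            )
    if p.utilities.hhf_disutility > 0:
        report.append("utilities.hhf_disutility: must be <= 0")

    # economics
    e = p.economics
    if e.annual_discount_rate_cost < 0 or e.annual_discount_rate_benefit < 0:
        report.append("economics: discount rates must be >= 0")
    if isinstance(e.horizon, str):
        if e.horizon != "lifetime":
            report.append(f"economics.horizon: {e.horizon!r} is not 'lifetime'")
    elif e.horizon <= 0:
        report.append("economics.horizon: must be > 0 months")
    if not (0 < e.starting_age < e.max_age):
        report.append("economics.starting_age: must be in (0, max_age)")

    # life table
    lt = p.life_table
    if not np.isclose(sum(lt.sex_mix.values()), 1.0):
        report.append("life_table.sex_mix: proportions must sum to 1")
    t = lt.table
    if ((t["annual_qx"] < 0) | (t["annual_qx"] > 1)).any():
        report.append("life_table.annual_qx: probabilities outside [0, 1]")
    if ((t["cv_share"] < 0) | (t["cv_share"] > 1)).any():
        report.append("life_table.cv_share: proportions outside [0, 1]")
    if lt.min_age > int(e.starting_age) or lt.max_age < int(e.max_age) - 1:
        report.append(
            f"life_table: ages {lt.min_age}-{lt.max_age} do not cover "
            f"starting age {e.starting_age} through max age {e.max_age}"
        )

    # combine spec
    c = p.combine
    if not math.isclose(c.weight_hfref + c.weight_ef40, 1.0):
        report.append("combine: weights must sum to 1")
    if sum(c.psa_resample_counts) != c.psa_total:
        report.append("combine: psa_resample_counts must sum to psa_total")

    return report


def require_valid(p: ModelParameters) -> ModelParameters:
    report = validate_parameters(p)
    if report:
        raise ConfigurationError(
            "invalid parameter bundle:\n  " + "\n  ".join(report)
        )
    return p


# ---------------------------------------------------------------------------
# Configuration I/O (YAML main file + CSV tables)
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "states", "economics", "costs", "utilities", "adverse_events",
    "hhf_model", "survival", "treatment_effect", "combine",
    "transition_matrices", "life_table", "sex_mix",
}
_SURV_KEYS = {"family", "intercept", "treatment_coef", "state_coefs",
              "ancillary", "reference_state"}
_AE_KEYS = {"rate_epg_soc", "rate_soc", "disutility", "unit_cost",
            "duration_months"}


def _check_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) at {path}: {sorted(unknown)}"
        )


def _parse_survival(d: dict, path: str) -> SurvivalSpec:
    _check_keys(d, _SURV_KEYS, path)
    for k in ("family", "intercept"):
        if k not in d:
            raise ConfigurationError(f"missing key {path}.{k}")
    return SurvivalSpec(
        family=str(d["family"]),
        intercept=float(d["intercept"]),
        treatment_coef=float(d.get("treatment_coef", 0.0)),
        state_coefs={k: float(v) for k, v in (d.get("state_coefs") or {}).items()},
        ancillary={k: float(v) for k, v in (d.get("ancillary") or {}).items()},
        reference_state=str(d.get("reference_state", REFERENCE_STATE)),
    )


def _read_transitions_csv(path: pathlib.Path) -> dict[tuple[str, str], np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["arm", "period", "from_state"] + list(ALIVE_STATES)
    if list(df.columns) != expected:
        raise DimensionError(
            f"{path.name}: columns {list(df.columns)} != {expected}"
        )
    out: dict[tuple[str, str], np.ndarray] = {}
    for (arm, period), g in df.groupby(["arm", "period"], sort=False):
        if list(g["from_state"]) != list(ALIVE_STATES):
            raise DimensionError(
                f"{path.name}: block ({arm}, {period}) must have one row per "
                f"state in order {list(ALIVE_STATES)}, got {list(g['from_state'])}"
            )
        out[(arm, period)] = g[list(ALIVE_STATES)].to_numpy(dtype=float)
    return out


def load_parameters(source: str | pathlib.Path) -> ModelParameters:
    """Read a parameter bundle from a configuration directory.

    ``source`` is the directory (or its ``config.yaml``).  The YAML file
    holds scalars and coefficients and references two CSV tables:
    transition matrices and the life table.  Unknown keys are rejected
    with their path; malformed tables raise a dimension error.
    """
    source = pathlib.Path(source)
    cfg_path = source / "config.yaml" if source.is_dir() else source
    if not cfg_path.exists():
        raise ConfigurationError(f"configuration file not found: {cfg_path}")
    base = cfg_path.parent
    with open(cfg_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{cfg_path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<top>")
    for section in ("economics", "costs", "utilities", "adverse_events",
                    "hhf_model", "survival", "transition_matrices", "life_table"):
        if section not in raw:
            raise ConfigurationError(f"missing configuration section: {section}")

    # states (optional; defaults to the canonical quartile bands)
    if "states" in raw:
        states = tuple(
            HealthStateDefinition(s["state_id"], float(s["kccq_lower"]),
                                  float(s["kccq_upper"]))
            for s in raw["states"]
        )
    else:
        states = default_health_states()

    econ_raw = dict(raw["economics"])
    _check_keys(econ_raw, {f.name for f in dataclasses.fields(EconomicConfig)},
                "economics")
    horizon = econ_raw.get("horizon", "lifetime")
    if horizon != "lifetime":
        econ_raw["horizon"] = int(horizon)
    economics = EconomicConfig(**econ_raw)

    costs_raw = dict(raw["costs"])
    _check_keys(costs_raw,
                {f.name for f in dataclasses.fields(CostSet)}, "costs")
    costs_raw["monthly_drug_cost"] = {
        k: float(v) for k, v in costs_raw["monthly_drug_cost"].items()
    }
    costs = CostSet(**costs_raw)

    util_raw = dict(raw["utilities"])
    _check_keys(util_raw, {f.name for f in dataclasses.fields(UtilityModel)},
                "utilities")
    util_raw["state_utility"] = {
        k: float(v) for k, v in util_raw["state_utility"].items()
    }
    utilities = UtilityModel(**util_raw)

    ae_raw = dict(raw["adverse_events"])
    include_dka = bool(ae_raw.pop("include_ketoacidosis", False))
    events: dict[str, AdverseEvent] = {}
    for name, d in ae_raw.items():
        _check_keys(d, _AE_KEYS, f"adverse_events.{name}")
        events[name] = AdverseEvent(
            name=name,
            monthly_rate={"EPG_SOC": float(d["rate_epg_soc"]),
                          "SOC": float(d["rate_soc"])},
            disutility=float(d["disutility"]),
            unit_cost=float(d["unit_cost"]),
            disutility_duration_months=float(d.get("duration_months", 1.0)),
        )
    adverse_events = AdverseEventProfile(events, include_ketoacidosis=include_dka)

    hhf_raw = dict(raw["hhf_model"])
    _check_keys(hhf_raw, {"intercept", "treatment_coef", "state_coefs",
                          "reference_state"}, "hhf_model")
    hhf = EventRateModel(
        intercept=float(hhf_raw["intercept"]),
        treatment_coef=float(hhf_raw.get("treatment_coef", 0.0)),
        state_coefs={k: float(v)
                     for k, v in (hhf_raw.get("state_coefs") or {}).items()},
        reference_state=str(hhf_raw.get("reference_state", REFERENCE_STATE)),
    )

    surv_raw = dict(raw["survival"])
    _check_keys(surv_raw, {"cv_death", "all_cause_death", "discontinuation"},
                "survival")
    cv = _parse_survival(surv_raw["cv_death"], "survival.cv_death")
    ac = _parse_survival(surv_raw["all_cause_death"], "survival.all_cause_death")
    disc = None
    if surv_raw.get("discontinuation") is not None:
        disc = _parse_survival(surv_raw["discontinuation"],
                               "survival.discontinuation")

    transitions = TransitionSchedule(
        _read_transitions_csv(base / raw["transition_matrices"])
    )

    lt_df = pd.read_csv(base / raw["life_table"], float_precision="round_trip")
    expected = ["age", "sex", "annual_qx", "cv_share"]
    if list(lt_df.columns) != expected:
        raise DimensionError(
            f"{raw['life_table']}: columns {list(lt_df.columns)} != {expected}"
        )
    sex_mix = {k: float(v) for k, v in raw.get(
        "sex_mix", {"male": 0.55, "female": 0.45}).items()}
    life_table = LifeTable(lt_df, sex_mix=sex_mix)

    te_raw = dict(raw.get("treatment_effect") or {})
    _check_keys(te_raw, {"hr_hhf_dsa", "subgroups"}, "treatment_effect")
    te = TreatmentEffect()
    if "hr_hhf_dsa" in te_raw:
        te.hr_hhf_dsa = tuple(float(v) for v in te_raw["hr_hhf_dsa"])
    if "subgroups" in te_raw:
        te.subgroups = {
            k: {kk: float(vv) for kk, vv in v.items()}
            for k, v in te_raw["subgroups"].items()
        }

    cmb_raw = dict(raw.get("combine") or {})
    _check_keys(cmb_raw, {f.name for f in dataclasses.fields(CombineSpec)},
                "combine")
    combine = CombineSpec(
        weight_hfref=float(cmb_raw.get("weight_hfref", 0.67)),
        weight_ef40=float(cmb_raw.get("weight_ef40", 0.33)),
        psa_resample_counts=tuple(
            int(v) for v in cmb_raw.get("psa_resample_counts", (670, 330))),
        psa_total=int(cmb_raw.get("psa_total", 1000)),
    )

    return ModelParameters(
        states=states, transitions=transitions, hhf=hhf, cv_death=cv,
        all_cause_death=ac, discontinuation=disc,
        adverse_events=adverse_events, costs=costs, utilities=utilities,
        economics=economics, life_table=life_table,
        treatment_effect=te, combine=combine,
    )


# -- writing ----------------------------------------------------------------


def _surv_to_dict(spec: SurvivalSpec | None) -> dict | None:
    if spec is None:
        return None
    return {
        "family": spec.family,
        "intercept": float(spec.intercept),
        "treatment_coef": float(spec.treatment_coef),
        "state_coefs": {k: float(v) for k, v in sorted(spec.state_coefs.items())},
        "ancillary": {k: float(v) for k, v in sorted(spec.ancillary.items())},
        "reference_state": spec.reference_state,
    }


def to_config_dict(p: ModelParameters) -> dict:
    """Canonical plain-data representation of the YAML portion of a bundle."""
    return {
        "states": [
            {"state_id": s.state_id, "kccq_lower": float(s.kccq_lower),
             "kccq_upper": float(s.kccq_upper)} for s in p.states
        ],
        "economics": {
            "annual_discount_rate_cost": float(p.economics.annual_discount_rate_cost),
            "annual_discount_rate_benefit": float(
                p.economics.annual_discount_rate_benefit),
            "cet": float(p.economics.cet),
            "cycle_length_months": float(p.economics.cycle_length_months),
            "horizon": p.economics.horizon,
            "starting_age": float(p.economics.starting_age),
            "half_cycle_correction": bool(p.economics.half_cycle_correction),
            "max_age": float(p.economics.max_age),
        },
        "costs": {
            "monthly_drug_cost": {k: float(v) for k, v in
                                  sorted(p.costs.monthly_drug_cost.items())},
            "hhf_cost": float(p.costs.hhf_cost),
            "cv_death_cost": float(p.costs.cv_death_cost),
            "noncv_death_cost": float(p.costs.noncv_death_cost),
            "monthly_disease_mgmt_cost": float(p.costs.monthly_disease_mgmt_cost),
            "currency_year": int(p.costs.currency_year),
        },
        "utilities": {
            "state_utility": {k: float(v) for k, v in
                              sorted(p.utilities.state_utility.items())},
            "hhf_disutility": float(p.utilities.hhf_disutility),
            "hhf_disutility_duration_months": float(
                p.utilities.hhf_disutility_duration_months),
        },
        "adverse_events": {
            "include_ketoacidosis": bool(p.adverse_events.include_ketoacidosis),
            **{
                name: {
                    "rate_epg_soc": float(ev.monthly_rate["EPG_SOC"]),
                    "rate_soc": float(ev.monthly_rate["SOC"]),
                    "disutility": float(ev.disutility),
                    "unit_cost": float(ev.unit_cost),
                    "duration_months": float(ev.disutility_duration_months),
                }
                for name, ev in sorted(p.adverse_events.events.items())
            },
        },
        "hhf_model": {
            "intercept": float(p.hhf.intercept),
            "treatment_coef": float(p.hhf.treatment_coef),
            "state_coefs": {k: float(v) for k, v in
                            sorted(p.hhf.state_coefs.items())},
            "reference_state": p.hhf.reference_state,
        },
        "survival": {
            "cv_death": _surv_to_dict(p.cv_death),
            "all_cause_death": _surv_to_dict(p.all_cause_death),
            "discontinuation": _surv_to_dict(p.discontinuation),
        },
        "treatment_effect": {
            "hr_hhf_dsa": [float(v) for v in p.treatment_effect.hr_hhf_dsa],
            "subgroups": {
                k: {kk: float(vv) for kk, vv in sorted(v.items())}
                for k, v in sorted(p.treatment_effect.subgroups.items())
            },
        },
        "combine": {
            "weight_hfref": float(p.combine.weight_hfref),
            "weight_ef40": float(p.combine.weight_ef40),
            "psa_resample_counts": [int(v) for v in p.combine.psa_resample_counts],
            "psa_total": int(p.combine.psa_total),
        },
        "sex_mix": {k: float(v) for k, v in sorted(p.life_table.sex_mix.items())},
        "transition_matrices": "transitions.csv",
        "life_table": "life_table.csv",
    }


def save_parameters(p: ModelParameters, directory: str | pathlib.Path) -> pathlib.Path:
    """Write a bundle to ``directory`` in canonical form.

    Canonical means sorted YAML keys and fixed CSV float formatting, so
    ``save(load(x))`` reproduces ``x`` byte for byte for files written by
    this function.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = to_config_dict(p)
    with open(directory / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)

    rows = []
    for arm in ARMS:
        for period in PERIODS:
            m = p.transitions.matrices[(arm, period)]
            for i, s in enumerate(ALIVE_STATES):
                rows.append({"arm": arm, "period": period, "from_state": s,
                             **{t: m[i, j] for j, t in enumerate(ALIVE_STATES)}})
    trans_df = pd.DataFrame(rows, columns=["arm", "period", "from_state",
                                           *ALIVE_STATES])
    trans_df.to_csv(directory / "transitions.csv", index=False,
                    float_format="%.17g", lineterminator="\n")

    lt = p.life_table.table[["age", "sex", "annual_qx", "cv_share"]]
    lt.to_csv(directory / "life_table.csv", index=False,
              float_format="%.17g", lineterminator="\n")
    return directory


def export_json(p: ModelParameters, path: str | pathlib.Path | None = None) -> str:
    """JSON export of the full validated bundle (tables inlined)."""
    d = to_config_dict(p)
    d["transition_matrices"] = {
        f"{arm}/{period}": p.transitions.matrices[(arm, period)].tolist()
        for arm in ARMS for period in PERIODS
    }
    d["life_table"] = p.life_table.table.to_dict(orient="list")
    text = json.dumps(d, indent=2, sort_keys=True)
    if path is not None:
        pathlib.Path(path).write_text(text, encoding="utf-8")
    return text
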