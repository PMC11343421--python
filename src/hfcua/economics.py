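"""Incremental cost-effectiveness, net benefit, CEACs and phenotype pooling.

Conventions: increments are intervention minus comparator; the ICER is
only reported as a ratio when the QALY increment is non-zero, otherwise a
dominance tag is used.  The probabilistic mean ICER is the ratio of mean
increments (not the mean of per-iteration ratios), so a degenerate PSA
reproduces the deterministic ICER exactly.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import OutcomeSummary

DOMINANT = "dominant"
DOMINATED = "dominated"
RATIO = "ratio"


@dataclass
class IncrementalResult:
    """Pairwise incremental outcomes (intervention minus comparator)."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    tag: str = RATIO

    @property
    def icer_per_qaly(self) -> float | None:
        if self.tag != RATIO or self.delta_qaly == 0.0:
            return None
        return self.delta_cost / self.delta_qaly

    @property
    def icer_per_ly(self) -> float | None:
        if self.tag != RATIO or self.delta_ly == 0.0:
            return None
        return self.delta_cost / self.delta_ly

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "tag": self.tag,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
        }


def _classify(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly <= 0:
        return DOMINATED
    if delta_qaly == 0.0:
        return DOMINANT if delta_cost < 0 else RATIO  # (0, 0): degenerate ratio-less
    return RATIO


def incremental(a: OutcomeSummary, b: OutcomeSummary) -> IncrementalResult:
    """Incremental result of arm ``a`` (intervention) versus ``b``."""
    dc = a.discounted.cost_total - b.discounted.cost_total
    dly = a.discounted.ly_total - b.discounted.ly_total
    dq = a.discounted.qaly_total - b.discounted.qaly_total
    return IncrementalResult(dc, dly, dq, tag=_classify(dc, dq))


def net_monetary_benefit(delta_cost: float, delta_qaly: float,
                         threshold: float) -> float:
    """NMB = threshold * dQALY - dCost; positive means cost-effective."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * delta_qaly - delta_cost


# ---------------------------------------------------------------------------
# Probabilistic samples
# ---------------------------------------------------------------------------

PSA_COLUMNS = ["iteration", "cost_epg_soc", "ly_epg_soc", "qaly_epg_soc",
               "cost_soc", "ly_soc", "qaly_soc"]


def psa_deltas(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-iteration (dCost, dLY, dQALY) arrays, intervention minus comparator."""
    dc = (samples["cost_epg_soc"] - samples["cost_soc"]).to_numpy()
    dly = (samples["ly_epg_soc"] - samples["ly_soc"]).to_numpy()
    dq = (samples["qaly_epg_soc"] - samples["qaly_soc"]).to_numpy()
    return dc, dly, dq


def ceac(samples: pd.DataFrame,
         threshold_grid: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the intervention arm.

    At each threshold, the fraction of iterations with strictly positive
    net monetary benefit (ties go to the comparator); the comparator's
    probability is the complement.
    """
    if len(samples) == 0:
        raise ValueError("CEAC requires at least one PSA sample")
    dc, _, dq = psa_deltas(samples)
    grid = np.asarray(threshold_grid, dtype=float)
    probs = np.array([(lam * dq - dc > 0).mean() for lam in grid])
    return pd.DataFrame({
        "threshold": grid,
        "p_intervention": probs,
        "p_comparator": 1.0 - probs,
    })


def psa_summary(samples: pd.DataFrame) -> dict:
    """Mean ICER (ratio of means) with 2.5/97.5 percentile intervals.

    If the mean QALY increment is zero, the ICER is undefined and a
    dominance tally is reported instead.
    """
    if len(samples) == 0:
        raise ValueError("PSA summary requires at least one sample")
    dc, dly, dq = psa_deltas(samples)
    out = {
        "n_iterations": int(len(samples)),
        "mean_delta_cost": float(dc.mean()),
        "mean_delta_ly": float(dly.mean()),
        "mean_delta_qaly": float(dq.mean()),
        "delta_cost_ci": [float(np.percentile(dc, 2.5)),
                          float(np.percentile(dc, 97.5))],
        "delta_qaly_ci": [float(np.percentile(dq, 2.5)),
                          float(np.percentile(dq, 97.5))],
    }
    if dq.mean() != 0.0:
        out["mean_icer_per_qaly"] = float(dc.mean() / dq.mean())
    else:
        out["mean_icer_per_qaly"] = None
        out["dominance_tally"] = {
            "dominant": int(((dc < 0) & (dq > 0)).sum()),
            "dominated": int(((dc > 0) & (dq <= 0)).sum()),
        }
    return out


def psa_mean_icer(samples: pd.DataFrame) -> float | None:
    return psa_summary(samples)["mean_icer_per_qaly"]


# ---------------------------------------------------------------------------
# Phenotype pooling
# ---------------------------------------------------------------------------


def companion_hfref_result() -> IncrementalResult:
    """Synthetic stand-in for the reduced-EF phenotype's base-case increments.

    The companion reduced-EF analysis published only its ICER (RM 20,364
    per QALY) and the pooled all-phenotype results; its cost and QALY
    increments are reconstructed here by inverting the published
    prevalence-weighted averages (weights 0.67/0.33).  Used when pooling
    the EF>40% results into an all-phenotype ICER.
    """
    delta_cost = (3747.0 - 0.33 * 3941.0) / 0.67
    delta_qaly = delta_cost / 20_364.0
    # the companion LY increment was not published; carried as QALY-scaled
    return IncrementalResult(delta_cost=delta_cost, delta_ly=delta_qaly,
                             delta_qaly=delta_qaly)


def combine_phenotypes_deterministic(r_hfref: IncrementalResult,
                                     r_ef40: IncrementalResult,
                                     spec) -> IncrementalResult:
    """Prevalence-weighted pooling of two phenotypes' incremental results.

    Pooled increments are the weighted means at full precision; the pooled
    ICER is pooled dCost / pooled dQALY.
    """
    w1, w2 = spec.weight_hfref, spec.weight_ef40
    dc = w1 * r_hfref.delta_cost + w2 * r_ef40.delta_cost
    dly = w1 * r_hfref.delta_ly + w2 * r_ef40.delta_ly
    dq = w1 * r_hfref.delta_qaly + w2 * r_ef40.delta_qaly
    return IncrementalResult(dc, dly, dq, tag=_classify(dc, dq))


def combine_phenotypes_psa(samples_hfref: pd.DataFrame,
                           samples_ef40: pd.DataFrame,
                           spec, seed: int) -> pd.DataFrame:
    """Pool PSA iterations across phenotypes by prevalence-weighted resampling.

    Draws the configured counts (without replacement) uniformly from each
    phenotype's iteration pool and concatenates them; reproducible under
    ``seed``.
    """
    n1, n2 = spec.psa_resample_counts
    if len(samples_hfref) < n1 or len(samples_ef40) < n2:
        raise ValueError(
            f"PSA pools ({len(samples_hfref)}, {len(samples_ef40)}) smaller "
            f"than resample counts ({n1}, {n2})"
        )
    rng = np.random.default_rng(seed)
    i1 = rng.choice(len(samples_hfref), size=n1, replace=False)
    i2 = rng.choice(len(samples_ef40), size=n2, replace=False)
    pooled = pd.concat(
        [samples_hfref.iloc[np.sort(i1)], samples_ef40.iloc[np.sort(i2)]],
        ignore_index=True,
    )
    pooled["iteration"] = np.arange(len(pooled))
    return pooled


def export_ceac(curve: pd.DataFrame, path: str | pathlib.Path) -> None:
    curve.to_csv(path, index=False, lineterminator="\n")


def export_scatter(samples: pd.DataFrame, path: str | pathlib.Path) -> None:
    """(dQALY, dCost) pairs for a cost-effectiveness plane scatter plot."""
    dc, _, dq = psa_deltas(samples)
    pd.DataFrame({"delta_qaly": dq, "delta_cost": dc}).to_csv(
        path, index=False, lineterminator="\n")
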