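"""Independent validation oracles for the cohort engine.

The microsimulation follows individual walkers through the same per-cycle
event probabilities the cohort model defines (death, discontinuation,
state transition), but stochastically: per stratum and cycle, binomial
draws split walkers over deaths and discontinuation and a multinomial
draw scatters survivors over destination states.  Exchangeability of
walkers within a stratum makes count-level sampling exactly equivalent to
looping over walkers one at a time.  Only the scalar probability
operations from the survival module are shared with the engine; the
propagation logic is written independently.
"""

from __future__ import annotations

import math

import numpy as np

from hfcua.parameters import ALIVE_STATES, ModelParameters
from hfcua.survival import (CyclicHazardContext, cycle_event_probability,
                            noncv_lifetable_probability)


def microsimulate(
    p: ModelParameters,
    arm: str,
    n_cycles: int,
    n_walkers: int,
    seed: int,
) -> np.ndarray:
    """Occupancy fractions, shape (n_cycles + 1, 10).

    Layout matches the engine trace: four on-treatment states, four
    off-treatment states, CV death, non-CV death.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(10, dtype=np.int64)
    per_state = n_walkers // 4
    layer = 0 if arm == "EPG_SOC" else 4
    for j in range(4):
        counts[layer + j] = per_state
    total = counts.sum()

    occ = np.zeros((n_cycles + 1, 10))
    occ[0] = counts / total

    for k in range(n_cycles):
        age = p.economics.starting_age + k / 12.0
        p_lt = noncv_lifetable_probability(p.life_table, age)
        new = np.zeros(10, dtype=np.int64)
        new[8], new[9] = counts[8], counts[9]
        period = p.transitions.period_for_cycle(k)

        for layer_idx, on in ((0, 1), (4, 0)):
            matrix = p.transitions.matrices[
                ("EPG_SOC" if on else "SOC", period)]
            for j, state in enumerate(ALIVE_STATES):
                n = int(counts[layer_idx + j])
                if n == 0:
                    continue
                ctx = CyclicHazardContext(
                    elapsed_time=float(k),
                    cycle_length=p.economics.cycle_length_months,
                    treatment=on, state=state)
                q_cv = cycle_event_probability(p.cv_death, ctx)
                q_ac = cycle_event_probability(p.all_cause_death, ctx)
                q_nc = max(max(0.0, q_ac - q_cv), p_lt)

                died_cv = rng.binomial(n, q_cv)
                alive = n - died_cv
                died_nc = rng.binomial(alive, q_nc)
                alive -= died_nc
                new[8] += died_cv
                new[9] += died_nc

                stay_on = on
                if on and p.discontinuation is not None and alive > 0:
                    q_d = cycle_event_probability(p.discontinuation, ctx)
                    moved = rng.binomial(alive, q_d)
                else:
                    moved = 0
                for group, n_group, dest_layer in (
                        ("kept", alive - moved, layer_idx),
                        ("moved", moved, 4)):
                    if n_group <= 0:
                        continue
                    dest_matrix = matrix if dest_layer == layer_idx else \
                        p.transitions.matrices[("SOC", period)]
                    dests = rng.multinomial(n_group, dest_matrix[j])
                    for jj in range(4):
                        new[dest_layer + jj] += dests[jj]
        counts = new
        occ[k + 1] = counts / total
    return occ


def microsim_se(occ_fraction: np.ndarray, n_walkers: int) -> np.ndarray:
    """Binomial standard error of each occupancy fraction."""
    pq = occ_fraction * (1.0 - occ_fraction)
    return np.sqrt(np.maximum(pq, 1e-12) / n_walkers)
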