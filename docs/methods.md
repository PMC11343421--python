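# Methods

## Model structure and assumptions

The engine is a cohort state-transition (Markov) model with monthly
cycles. The state space is the product of four alive KCCQ-CSS quartile
states (Q1 worst … Q4 best; cut points 55.73 / 73.96 / 88.02 from the
trial population's score distribution) and on/off-treatment status, plus
two absorbing death states (CV, non-CV). The comparator arm lives
entirely in the off-treatment layer. The cohort enters 25% in each
quartile at a starting age of 64.6 years (local registry mean for EF>40%
heart failure).

Within-cycle event order is fixed and documented rather than inherited:
death first (so patients cannot die out of a state they left mid-cycle),
then discontinuation, then quartile transition, with transient events
accruing to the post-death alive occupancy. Cessation of the
intervention immediately switches a patient to comparator risks, costs
and utilities; there is no washout.

The "lifetime" horizon runs to age 100 or until total alive occupancy
falls below 1e-6, whichever comes first; finite horizons are clamped to
the life-table range with a warning.

## Time-to-event processes

Six parametric families are supported. Weibull, lognormal, log-logistic
and generalised gamma use accelerated-failure-time (AFT) coding — the
covariate linear predictor is the log-time location — while exponential
and Gompertz use proportional-hazards coding (log-hazard). This split
matches the output conventions of standard survival-regression software
so externally fitted coefficients can be transcribed directly; the
bundle's survival section records family and coefficients together, so a
convention mismatch cannot occur silently. The generalised gamma uses
the Prentice (μ, σ, Q) parameterisation, which nests Weibull (Q = 1,
shape 1/σ) and lognormal (Q = 0); both reductions are verified
numerically in the test suite.

Per-cycle conditional probabilities are 1 − S(t+Δ)/S(t) with the
covariates (treatment status, current quartile) frozen over the cycle —
the piecewise-constant covariate approximation, unavoidable in a cohort
model that cannot track within-cycle switching.

Competing mortality risks are resolved CV-first: the CV risk equation
removes mass, then the non-CV probability applies to the CV survivors.
The trial-based non-CV probability is max(0, p_all-cause − p_CV) — the
subtraction can go negative when the curves cross, and is floored with a
logged warning — and each cycle the engine uses the larger of that and
the life-table non-CV probability (annual q_x × (1 − CV share),
sex-mix-weighted, converted to monthly via 1 − (1−p)^(1/12)). The
cohort ages continuously (age = start + t/12) with integer-age table
lookup. The intervention affects CV death only; all-cause death carries
no treatment coefficient, so its benefit flows through the CV pathway —
removing it (HR → 1) is a one-line override used in DSA and a scenario.

## Accrual, discounting, reporting

State-based quantities (life-years, state utilities, drug and
disease-management cost) use half-cycle-corrected occupancy — the mean
of cycle-start and cycle-end. Event-based quantities (hHF, adverse
events, death costs, event disutilities) apply in full in their cycle;
half-cycle correction is applied to occupancy only. Discounting is
(1+r)^(−k/12) at cycle k, base 3%/year for both costs and benefits.

Event utility decrements are one-off: 0.335 QALYs per hospitalisation
(decrement −0.335 held for 12 months — the only reading consistent with
the published per-arm "loss due to hHF" given the printed event rates)
and |disutility|/12 per adverse event (one month). hHF uses
expected-count (Poisson) accounting with no per-patient cap. Drug cost
accrues at the intervention price only to on-treatment occupancy;
off-treatment and comparator occupancy pay the comparator price. CV
deaths cost RM 2,573 each at the cycle of death; non-CV deaths are free.
Event rates per 100 person-years divide undiscounted event totals by
undiscounted (half-cycle-corrected) alive person-years.

Internal computation is full double precision; printed tables round as
published (whole RM, rates to 2 dp).

## Economics

Increments are intervention minus comparator. Dominance: cheaper and
more effective → dominant; dearer and no more effective → dominated; a
ratio is only reported when ΔQALY ≠ 0. The probabilistic mean ICER is
the ratio of mean increments, not the mean of ratios — the convention
under which a degenerate PSA reproduces the deterministic ICER exactly.
CEAC probabilities count strictly positive net monetary benefit, ties to
the comparator, so the two arms' curves partition to 1.

Phenotype pooling weights increments 0.67 (reduced EF) / 0.33 (EF>40%),
the phenotypes' local prevalence shares; the pooled ICER is the ratio of
pooled increments at full precision. Probabilistic pooling resamples
670 + 330 iterations uniformly *without* replacement — at these counts
that preserves the empirical marginals better than with-replacement
sampling. The companion reduced-EF study's increments were not published
beyond its ICER (RM 20,364/QALY); `economics.companion_hfref_result()`
reconstructs them by inverting the published pooled weighted averages
and is labelled a synthetic stand-in.

## Sensitivity layers

**DSA** varies one parameter at a time over printed confidence bounds
(hHF rate ratio 0.69–0.83; CV-death HR up to 1) or ±20% for costs and
±10% for utilities, the latter clipped so quartile-utility monotonicity
survives; bars are sorted by ICER spread and flagged when they cross the
threshold. An override producing an invalid bundle marks the row failed
and the run continues.

**PSA** (default 1,000 iterations) samples all inputs jointly: beta
(moment-matched, SE = 10% of mean) for utilities and event
probabilities, gamma (SE = 20%) for costs, lognormal for treatment
ratios (hHF σ from the printed 0.69–0.90 CI; CV-death σ = 0.09, an
assumption), Dirichlet (concentration 100 × base row) on every
transition row. Independent utility draws can break the strict Q1<…<Q4
ordering; the utility block is redrawn (cap 100) rather than sorted, to
avoid biasing the marginals. All randomness flows through one
`numpy` generator seeded explicitly; runs are bitwise reproducible.

**Scenarios** cover discount rates 0/5%, horizons 5/10 years, starting
age 71.9, survival-family swaps for mortality and discontinuation,
no-discontinuation, ketoacidosis inclusion, removed CV benefit and the
T2D / non-T2D subgroups (HRs 1.01/0.78 and 0.83/0.77, shared transition
matrices). Family swaps cannot reuse coefficients across conventions,
so the swapped family's intercept and treatment coefficient are
re-calibrated to reproduce the base bundle's modelled per-100-PY rates
(or mean treatment duration): families then differ in tail behaviour,
not in horizon-average event rates. Exact hazard-ratio overrides exist
only for PH families and the Weibull AFT (coef = −ln HR / shape); other
AFT families reject HR ≠ 1 rather than approximate.

## Synthetic data generation and calibration

The generator stands in for unpublished fitted inputs; everything
published verbatim (utilities 0.613/0.707/0.778/0.832, disutilities,
all costs, discount rates, threshold, weights) is used verbatim.

* **Transition matrices**: comparator rows drawn from a Dirichlet
  (concentration 600) centred on mean reversion with a mild
  disease-progression tilt; the intervention effect is a fixed log-odds
  shift toward better states, strongest in months 1–3 (0.22/0.12/0.06 by
  period), mimicking the early health-status response seen in trials.
* **Risk equations**: Weibull AFT mortality (shapes 1.1/1.15 — gently
  increasing hazard), generalised-gamma discontinuation (σ = 0.9,
  Q = 1.2), log-linear Poisson hHF with state rate ratios 1.8/1.4/1.15
  vs Q4.
* **Adverse events**: monthly rates set to the published per-100-PY
  rates /1200; ketoacidosis (scenario-only) has no published inputs and
  uses synthetic assumptions (0.5/0.2 per 100 PY, −0.05, RM 3,000).
* **Life table**: Gompertz mortality (q_x = 3.4e-5·e^(0.094·age), women
  ×0.78) with a small seeded jitter, monotonicity enforced; CV share of
  deaths declines linearly within 0.2–0.5.

Calibration root-finds (Brent) one coefficient per target — comparator
intercepts, intervention treatment coefficients, the discontinuation
location — against the whole-model per-100-PY rates. Because the
targets interact (mortality sets person-years; discontinuation sets
intervention exposure), the pass repeats until all six targets hold
jointly within 0.2% (typically 2–3 passes, a few seconds).

What the synthetic bundle does **not** emulate: patient-level KCCQ
trajectories, parameter covariance, treatment-by-covariate interactions,
and the real national life table. Passing tests therefore demonstrate
the engine's correctness and the calibration's fidelity to the published
aggregate rates, not agreement of every downstream table with the
published analysis — the base-case ICER computed here lands near, but
not at, the published figure, as expected when transition matrices and
risk-equation shapes are stand-ins.

## Validation oracle and problem sizes

The cohort engine is validated against an independent individual-level
microsimulation (200,000 walkers, binomial/multinomial count sampling
per stratum and cycle — exactly equivalent to walker-by-walker
simulation by exchangeability) on 60-month runs; occupancy agrees within
3 Monte-Carlo standard errors at months 6, 12 and 60 in both arms.
Closed forms (geometric life expectancy, memoryless cycle probabilities,
telescoping survival products, discount factors) pin the elementary
operations. The test suite favours short horizons and small PSA runs
(n ≤ 10) as its working sizes; the acceptance script runs the full
lifetime horizon (425 cycles) and the full 1,000-iteration PSA.

## Known limitations

Costs are floats tagged with a currency year (all published inputs are
whole RM, exactly representable). The procurement-price scenario from
the published analysis is not reproducible (prices undisclosed). No
EVPI/EVSI, no more than two arms, no device costs, and no fitting of
risk equations from patient-level data — the package evaluates supplied
coefficients.
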