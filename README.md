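# hfcua

A Markov cohort cost-utility model for adding an SGLT2 inhibitor
(empagliflozin) to standard of care in chronic heart failure with
ejection fraction > 40%, from the perspective of the Malaysian public
healthcare payer. The package is aimed at health-economic modellers and
HTA analysts: it exposes the full pipeline — parameter bundles, cohort
propagation, incremental cost-effectiveness, deterministic/probabilistic
sensitivity analyses, scenario and subgroup runs, and prevalence-weighted
pooling across heart-failure phenotypes — as an importable Python library
with a thin CLI.

## The model

Patients occupy one of four alive health states defined by quartiles of
the Kansas City Cardiomyopathy Questionnaire clinical summary score
(KCCQ-CSS: 0–<55.73, <73.96, <88.02, ≤100), crossed with on/off-treatment
status, plus cardiovascular (CV) and non-CV death. Monthly cycles run
over a lifetime horizon. Each cycle, in order:

1. **death** — CV death from a parametric risk equation (Weibull AFT in
   the base case, with treatment and health-state covariates); non-CV
   death as max(all-cause − CV, general-population life-table non-CV
   rate), so modelled patients are never healthier than the background
   population;
2. **treatment discontinuation** (generalised-gamma time-to-event);
   discontinued patients face comparator risks, costs and utilities;
3. **transition** among KCCQ-CSS quartiles via three-period (months 1–3,
   4–8, 9+), treatment-specific row-stochastic matrices;
4. **transient events** — heart-failure hospitalisations (hHF, Poisson
   log-rate model) and adverse events accrue as expected counts.

Life-years, state utilities and drug/disease-management costs are
half-cycle corrected; events carry one-off costs and utility decrements
(−0.335 over 12 months per hHF, one month per adverse event). Costs
(2022 RM) and QALYs are discounted at 3%/year:

ICER = ΔC/ΔQ, NMB(λ) = λ·ΔQ − ΔC, with a cost-effectiveness threshold
λ = RM 47,439 per QALY.

Because the trial-derived coefficient tables are not publicly deposited,
`hfcua.synthetic` generates internally consistent stand-in bundles and
calibrates them by root-finding so the whole model reproduces the
published event rates (comparator hHF 8.45 and CV death 5.12 per 100
person-years; intervention 7.31 and 4.84; 3.34 years mean time on
treatment). A calibrated seed-0 bundle ships as
`src/hfcua/data/synthetic_basecase/`.

## Worked example

```python
from hfcua import economics, engine, synthetic

bundle = synthetic.calibrated_bundle(synthetic.SyntheticSpec(seed=0))
epg = engine.run_arm(bundle, "EPG_SOC")
soc = engine.run_arm(bundle, "SOC")
result = economics.incremental(epg, soc)
print(f"dCost RM {result.delta_cost:,.0f}  dQALY {result.delta_qaly:.3f}"
      f"  ICER RM {result.icer_per_qaly:,.0f}/QALY")
```

prints

```
dCost RM 3,848  dQALY 0.092  ICER RM 41,740/QALY
```

i.e. adding the drug costs RM 3,848 extra per patient over a lifetime,
buys 0.092 quality-adjusted life-years, and the ratio sits below the
RM 47,439/QALY threshold — cost-effective. The scripts in `examples/`
walk through the base case, the sensitivity layers (tornado, scenarios,
PSA/CEAC) and phenotype pooling; the `hfcua` console command exposes the
same steps from a shell (`hfcua run --config src/hfcua/data/synthetic_basecase --out out/`).

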