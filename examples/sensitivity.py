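"""Sensitivity analyses: tornado diagram data, scenarios, and a short PSA.

Shows which inputs move the ICER most (one-way DSA), how structural
choices shift it (scenarios), and how joint parameter uncertainty
translates into a probability of cost-effectiveness (PSA + CEAC).
"""

import numpy as np

from hfcua import economics, synthetic, uncertainty

bundle = synthetic.calibrated_bundle(synthetic.SyntheticSpec(seed=0))
cet = bundle.economics.cet

# --- one-way deterministic sensitivity (tornado) -----------------------
tornado = uncertainty.run_dsa(bundle, uncertainty.default_dsa_specs(bundle))
print("Tornado (top 5 bars, ICER range in RM/QALY):")
for _, row in tornado.head(5).iterrows():
    print(f"  {row['parameter']:<34} {row['icer_low']:>9,.0f} .. "
          f"{row['icer_high']:>9,.0f}"
          f"{'   crosses CET' if row['crosses_cet'] else ''}")

# --- scenarios ----------------------------------------------------------
scenarios = [s for s in uncertainty.default_scenarios(bundle)
             if s.name in ("horizon_5y", "discount_0pct", "discount_5pct",
                           "no_cv_benefit", "subgroup_t2d")]
table = uncertainty.run_scenarios(bundle, scenarios)
print("\nScenarios (ICER and % change from base):")
for _, row in table.iterrows():
    print(f"  {row['scenario']:<18} RM {row['icer_per_qaly']:>9,.0f}"
          f"  ({row['pct_change']:+.0f}%)")

# --- probabilistic sensitivity analysis --------------------------------
samples, _ = uncertainty.run_psa(bundle, n=100, seed=1)
summary = economics.psa_summary(samples)
curve = economics.ceac(samples, np.array([0.0, cet, 2 * cet]))
print(f"\nPSA ({summary['n_iterations']} iterations):")
print(f"  mean ICER          RM {summary['mean_icer_per_qaly']:,.0f} /QALY")
print(f"  dCost 95% interval RM {summary['delta_cost_ci'][0]:,.0f} "
      f"to RM {summary['delta_cost_ci'][1]:,.0f}")
print(f"  P(cost-effective)  {curve['p_intervention'].iloc[1]:.0%} "
      f"at the RM {cet:,.0f}/QALY threshold")
# The CEAC value is the share of Monte-Carlo replications in which the
# intervention's net monetary benefit is positive at that threshold.
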