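"""Pooling the EF>40% result with the reduced-EF phenotype.

Heart failure spans ejection-fraction phenotypes; a payer deciding on
whole-population reimbursement needs the prevalence-weighted result
(0.67 reduced EF / 0.33 EF>40% locally).  Deterministic pooling weights
the cost and QALY increments; probabilistic pooling resamples 670 + 330
PSA iterations from the two phenotypes' pools.
"""

from hfcua import economics, synthetic, uncertainty

bundle = synthetic.calibrated_bundle(synthetic.SyntheticSpec(seed=0))

ef40 = uncertainty.deterministic_icer(bundle)
hfref = economics.companion_hfref_result()  # reconstructed increments
pooled = economics.combine_phenotypes_deterministic(hfref, ef40,
                                                    bundle.combine)
print("Deterministic pooling (weights 0.67 reduced-EF / 0.33 EF>40%):")
print(f"  EF>40%   dCost RM {ef40.delta_cost:,.0f}, dQALY "
      f"{ef40.delta_qaly:.3f}, ICER RM {ef40.icer_per_qaly:,.0f}")
print(f"  red.-EF  dCost RM {hfref.delta_cost:,.0f}, dQALY "
      f"{hfref.delta_qaly:.3f}, ICER RM {hfref.icer_per_qaly:,.0f}")
print(f"  pooled   dCost RM {pooled.delta_cost:,.0f}, dQALY "
      f"{pooled.delta_qaly:.3f}, ICER RM {pooled.icer_per_qaly:,.0f}")

# Probabilistic pooling needs per-phenotype PSA pools at least as large as
# the resample counts; here both pools come from this model for
# illustration (a real pooling would load the companion study's samples).
spec = bundle.combine
spec.psa_resample_counts = (20, 10)
spec.psa_total = 30
pool_a, _ = uncertainty.run_psa(bundle, n=25, seed=1)
pool_b, _ = uncertainty.run_psa(bundle, n=15, seed=2)
merged = economics.combine_phenotypes_psa(pool_a, pool_b, spec, seed=3)
summary = economics.psa_summary(merged)
print(f"\nProbabilistic pooling ({len(merged)} resampled iterations):")
print(f"  pooled mean ICER RM {summary['mean_icer_per_qaly']:,.0f} per QALY")
# A pooled ICER below the threshold supports reimbursing the drug for the
# whole heart-failure population rather than one phenotype only.
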