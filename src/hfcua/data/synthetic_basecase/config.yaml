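adverse_events:
  acute_renal_failure:
    disutility: -0.013
    duration_months: 1.0
    rate_epg_soc: 0.005875
    rate_soc: 0.00605
    unit_cost: 3185.0
  bone_fracture:
    disutility: -0.156
    duration_months: 1.0
    rate_epg_soc: 0.001975
    rate_soc: 0.0019166666666666666
    unit_cost: 3523.0
  genital_infection:
    disutility: -0.038
    duration_months: 1.0
    rate_epg_soc: 0.0006833333333333333
    rate_soc: 0.000325
    unit_cost: 320.0
  hepatic_injury:
    disutility: -0.042
    duration_months: 1.0
    rate_epg_soc: 0.0020250000000000003
    rate_soc: 0.0023666666666666667
    unit_cost: 3230.0
  hypoglycaemia:
    disutility: -0.002
    duration_months: 1.0
    rate_epg_soc: 0.0011333333333333334
    rate_soc: 0.0011749999999999998
    unit_cost: 693.0
  hypotension:
    disutility: -0.025
    duration_months: 1.0
    rate_epg_soc: 0.004483333333333333
    rate_soc: 0.004
    unit_cost: 1282.0
  include_ketoacidosis: false
  ketoacidosis:
    disutility: -0.05
    duration_months: 1.0
    rate_epg_soc: 0.0004166666666666667
    rate_soc: 0.0001666666666666667
    unit_cost: 3000.0
  urinary_tract_infection:
    disutility: -0.04
    duration_months: 1.0
    rate_epg_soc: 0.004233333333333334
    rate_soc: 0.003775
    unit_cost: 213.0
  volume_depletion:
    disutility: -0.026
    duration_months: 1.0
    rate_epg_soc: 0.005108333333333334
    rate_soc: 0.004483333333333333
    unit_cost: 984.0
combine:
  psa_resample_counts:
  - 670
  - 330
  psa_total: 1000
  weight_ef40: 0.33
  weight_hfref: 0.67
costs:
  currency_year: 2022
  cv_death_cost: 2573.0
  hhf_cost: 5276.0
  monthly_disease_mgmt_cost: 28.0
  monthly_drug_cost:
    EPG_SOC: 212.0
    SOC: 101.0
  noncv_death_cost: 0.0
economics:
  annual_discount_rate_benefit: 0.03
  annual_discount_rate_cost: 0.03
  cet: 47439.0
  cycle_length_months: 1.0
  half_cycle_correction: true
  horizon: lifetime
  max_age: 100.0
  starting_age: 64.6
hhf_model:
  intercept: -5.243587414575386
  reference_state: Q4
  state_coefs:
    Q1: 0.5877866649021191
    Q2: 0.3364722366212129
    Q3: 0.13976194237515863
  treatment_coef: -0.2620768701486685
life_table: life_table.csv
sex_mix:
  female: 0.45
  male: 0.55
states:
- kccq_lower: 0.0
  kccq_upper: 55.73
  state_id: Q1
- kccq_lower: 55.73
  kccq_upper: 73.96
  state_id: Q2
- kccq_lower: 73.96
  kccq_upper: 88.02
  state_id: Q3
- kccq_lower: 88.02
  kccq_upper: 100.0
  state_id: Q4
survival:
  all_cause_death:
    ancillary:
      shape: 1.15
    family: weibull
    intercept: 4.612316699672446
    reference_state: Q4
    state_coefs:
      Q1: -0.5
      Q2: -0.3
      Q3: -0.15
    treatment_coef: 0.0
  cv_death:
    ancillary:
      shape: 1.1
    family: weibull
    intercept: 5.650678586239387
    reference_state: Q4
    state_coefs:
      Q1: -0.5
      Q2: -0.3
      Q3: -0.15
    treatment_coef: 0.08146198339247943
  discontinuation:
    ancillary:
      q: 1.2
      sigma: 0.9
    family: gengamma
    intercept: 4.501908591409373
    reference_state: Q4
    state_coefs:
      Q1: -0.2
      Q2: -0.1
      Q3: -0.05
    treatment_coef: 0.0
transition_matrices: transitions.csv
treatment_effect:
  hr_hhf_dsa:
  - 0.69
  - 0.83
  subgroups:
    non_t2d:
      hr_cv_death: 0.83
      rr_hhf: 0.77
    t2d:
      hr_cv_death: 1.01
      rr_hhf: 0.78
utilities:
  hhf_disutility: -0.335
  hhf_disutility_duration_months: 12.0
  state_utility:
    Q1: 0.613
    Q2: 0.707
    Q3: 0.778
    Q4: 0.832
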