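schema_version: 1
scalars:
  discount_rate_costs: 0.03
  discount_rate_effects: 0.03
  sek_per_eur: 9.0335
  cycle_length_months: 6.0
  treatment_duration_months: 18.0
  history_window_years: 5.0
  hazard_composition: probability
  days_per_cycle: 182.625
second_fracture_increase:
  GIOP: 0.5
  PMO: 1.0
bmd_gradient:
  hip: 2.6
  vertebral: 1.8
  wrist: 1.4
fracture_after_fracture_rr:
  hip: 2.0
  vertebral: 2.3
  wrist: 1.4
efficacy:
  teriparatide:
    vertebral:
      on_treatment_rr: 0.17
      sustained_rr: 0.43
      sustained_months: 18.0
      offset_months: 18.0
    hip:
      on_treatment_rr: 0.47
      sustained_rr: 0.73
      sustained_months: 30.0
      offset_months: 18.0
    wrist:
      on_treatment_rr: 0.47
      sustained_rr: 0.73
      sustained_months: 30.0
      offset_months: 18.0
  bisphosphonate:
    hip:
      on_treatment_rr: 0.77
      sustained_rr: 0.77
      sustained_months: 0.0
      offset_months: 18.0
    vertebral:
      on_treatment_rr: 0.56
      sustained_rr: 0.56
      sustained_months: 0.0
      offset_months: 18.0
    wrist:
      on_treatment_rr: 0.77
      sustained_rr: 0.77
      sustained_months: 0.0
      offset_months: 18.0
drug_daily_eur:
  teriparatide: 14.74
  bisphosphonate: 0.42
  none: 0.0
visit_basic_eur: 194.0
visit_bmd_eur: 201.0
excess_schedule:
  hip:
  - 2.5
  - 2.25
  - 2.0
  - 1.75
  - 1.5
  - 1.25
  - 1.0
  vertebral:
  - 2.5
  - 2.2
  - 1.9
  - 1.6
  - 1.3
  - 1.0
discontinuation:
  teriparatide:
  - 1.0
  - 0.9
  - 0.83
  bisphosphonate:
  - 1.0
  - 0.7
  - 0.55
utility_multipliers:
  first_year:
    hip: 0.697
    vertebral: 0.626
    wrist: 0.977
  subsequent:
    hip: 0.813
    vertebral: 0.909
    wrist: 0.999
  repeat_q: 0.25
  repeat_rule: multiplicative
provenance:
  baseline_risks: placeholder
  male_female_ratio: placeholder
  mean_t_score: placeholder
  giop_rr: placeholder
  bmd_gradient: placeholder
  fracture_after_fracture_rr: placeholder
  life_table: placeholder
  fracture_death_proportion: placeholder
  fracture_mortality: placeholder
  excess_schedule: packaged-default
  fracture_costs: placeholder
  drug_daily_eur: packaged-default
  visit_costs: packaged-default
  base_utilities: packaged-default
  utility_multipliers: placeholder
  efficacy.teriparatide: packaged-default
  efficacy.bisphosphonate: placeholder
  discontinuation: placeholder
  scalars: packaged-default
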