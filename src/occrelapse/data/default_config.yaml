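# Default analysis configuration: three paliperidone formulation profiles,
# the five-trial discontinuation program structure, and the generative
# hazard used for simulation studies.
formulations:
  oral:
    ed50_mg_per_day: 2.38
    half_life_days: 1.0        # governs oral placebo washout only
    trough_occupancy_pct: 80.0
    max_occupancy_pct: 100.0
  lai_1m:
    ed50_mg_per_day: 2.38
    half_life_days: 37.0
    time_to_peak_days: 5.0
    dosing_interval_days: 30.0
    trough_occupancy_pct: 80.0
    max_occupancy_pct: 100.0
  lai_3m:
    ed50_mg_per_day: 2.38
    half_life_days: 111.5
    time_to_peak_days: 28.0
    dosing_interval_days: 90.0
    trough_occupancy_pct: 80.0
    max_occupancy_pct: 100.0

trials:
  - {trial_id: lai3m_A, formulation: lai_3m, n_active: 159, n_placebo: 144,
     max_followup_days: 487, dropout_hazard_per_day: 0.0006}
  - {trial_id: lai1m_A, formulation: lai_1m, n_active: 164, n_placebo: 170,
     max_followup_days: 487, dropout_hazard_per_day: 0.0006}
  - {trial_id: lai1m_B, formulation: lai_1m, n_active: 205, n_placebo: 203,
     max_followup_days: 487, dropout_hazard_per_day: 0.0006}
  - {trial_id: oral_A, formulation: oral, n_active: 105, n_placebo: 102,
     max_followup_days: 365, dropout_hazard_per_day: 0.0006}
  - {trial_id: oral_B, formulation: oral, n_active: 65, n_placebo: 71,
     max_followup_days: 426, dropout_hazard_per_day: 0.0006}

hazard:
  baseline_hazard_per_day: 0.005
  beta_group: 0.0
  beta_occ_per_10pct: -0.34
  beta_rate: 0.0
  beta_time_interaction_per_day: 0.0

analysis:
  base_ratio: 100
  trough_occupancy_grid: [75.0, 80.0, 85.0]
  occupancy_scale_pct: 10
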