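{
  "n_patients": 150,
  "horizon": 84,
  "block_sizes": [2, 4, 6],
  "hospitals": ["academic_A", "academic_B", "community_A", "community_B"],
  "hospital_weights": [0.35, 0.3, 0.2, 0.15],
  "new_onset_prob": 0.3,
  "dropout_prob": 0.05,
  "baseline_medication_rates": {
    "RASI": 0.906,
    "ARNI_given_RASI": 0.47,
    "BETA_BLOCKER": 0.79,
    "MRA": 0.64,
    "SGLT2I": 0.567
  },
  "dose_fraction_grid": [0.25, 0.5, 1.0],
  "dose_fraction_weights": {
    "RASI": [0.3, 0.4, 0.3],
    "BETA_BLOCKER": [0.1, 0.25, 0.65],
    "MRA": [0.25, 0.35, 0.4]
  },
  "iron": {
    "baseline_screened_prob": 0.31,
    "deficiency_prob": 0.64,
    "baseline_iv_given_prob": 0.3,
    "followup_iv_given_prob": 0.85
  },
  "lab_distributions": {
    "potassium": {"mean": 4.26, "sd": 0.45, "visit_sd": 0.25},
    "egfr_log": {"mean": 4.205, "sd": 0.49, "visit_sd": 0.08},
    "ferritin_log": {"mean": 4.7, "sd": 0.8},
    "tsat": {"mean": 20.0, "sd": 8.0},
    "hb": {"mean": 13.2, "sd": 1.9}
  },
  "vitals_distributions": {
    "systolic_bp": {"mean": 125.0, "sd": 15.0, "reading_sd": 8.0},
    "diastolic_bp": {"mean": 75.0, "sd": 9.0, "reading_sd": 6.0},
    "heart_rate": {"mean": 72.0, "sd": 11.0, "reading_sd": 5.0},
    "weight": {"mean": 83.0, "sd": 15.0, "reading_sd": 0.8}
  },
  "covariates": {
    "age": {"mean": 67.0, "sd": 11.0, "min": 22, "max": 95},
    "nyha3_prob": 0.235,
    "ischemic_prob": 0.49,
    "nurse_support_prob": 0.5
  },
  "consult_rate": {
    "DC": {"remote": 2.4, "physical": 1.2},
    "USUAL": {"remote": 1.3, "physical": 1.4}
  },
  "uptitration_prob_per_consult": {"DC": 0.2, "USUAL": 0.08},
  "iron_screening_prob_per_consult": {"DC": 0.35, "USUAL": 0.05},
  "allergy_prob_per_class": 0.01,
  "symptomatic_hypotension_prob": 0.03,
  "hospitalization_rate": 0.11,
  "questionnaires": {
    "kccq_baseline": {"mean": 62.0, "sd": 18.0},
    "kccq_change": {"mean": 2.5, "sd": 11.0},
    "nps_baseline_probs": [0.01, 0.01, 0.02, 0.03, 0.05, 0.08, 0.2, 0.3, 0.2, 0.1],
    "time_spent_log": {"mean": 1.0, "sd": 0.6}
  },
  "seed": 0
}
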