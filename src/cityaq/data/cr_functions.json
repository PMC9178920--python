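[
  {"endpoint": "adult_mortality", "variant": "low", "beta": 0.0058, "age_min": 30, "age_max": 99},
  {"endpoint": "adult_mortality", "variant": "high", "beta": 0.0130, "age_min": 30, "age_max": 99},
  {"endpoint": "infant_mortality", "variant": "single", "beta": 0.0039, "age_min": 0, "age_max": 0},
  {"endpoint": "nonfatal_heart_attacks", "variant": "low", "beta": 0.0006, "age_min": 18, "age_max": 99},
  {"endpoint": "nonfatal_heart_attacks", "variant": "high", "beta": 0.0053, "age_min": 18, "age_max": 99},
  {"endpoint": "respiratory_hospitalizations", "variant": "single", "beta": 0.0007, "age_min": 0, "age_max": 99},
  {"endpoint": "cardiovascular_hospitalizations", "variant": "single", "beta": 0.0009, "age_min": 18, "age_max": 99},
  {"endpoint": "acute_bronchitis", "variant": "single", "beta": 0.0272, "age_min": 8, "age_max": 12},
  {"endpoint": "upper_respiratory_symptoms", "variant": "single", "beta": 0.0036, "age_min": 9, "age_max": 11},
  {"endpoint": "lower_respiratory_symptoms", "variant": "single", "beta": 0.0190, "age_min": 7, "age_max": 14},
  {"endpoint": "asthma_ed_visits", "variant": "single", "beta": 0.0056, "age_min": 0, "age_max": 99},
  {"endpoint": "asthma_exacerbations", "variant": "single", "beta": 0.0019, "age_min": 6, "age_max": 18},
  {"endpoint": "minor_restricted_activity_days", "variant": "single", "beta": 0.0074, "age_min": 18, "age_max": 64},
  {"endpoint": "work_loss_days", "variant": "single", "beta": 0.0046, "age_min": 18, "age_max": 64}
]
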