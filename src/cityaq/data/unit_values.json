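{
  "adult_mortality": 9000000,
  "infant_mortality": 9000000,
  "nonfatal_heart_attacks": 120000,
  "respiratory_hospitalizations": 35000,
  "cardiovascular_hospitalizations": 45000,
  "acute_bronchitis": 500,
  "upper_respiratory_symptoms": 35,
  "lower_respiratory_symptoms": 22,
  "asthma_ed_visits": 450,
  "asthma_exacerbations": 60,
  "minor_restricted_activity_days": 70,
  "work_loss_days": 160
}
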