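# Default pipeline run: 26 ASD + 15 TD + 4 adult subjects x 6 trials at 100 Hz.
simulate:
  n_subjects:
    ASD: 26
    TD: 15
    ADULT: 4
  trials_per_subject: 6
  sampling_rate_hz: 100
  trial_dropout: 0.0
  # per-group generative profiles may be overridden field-by-field, e.g.
  # profiles:
  #   ASD:
  #     n_corrective_mean: 6.0

kinematics:
  filter: butterworth      # or "none"
  cutoff_hz: 10
  order: 4
  threshold_fraction: 0.2  # onset rule: both signals at 20% of window max
  hysteresis_fraction: 0.01
  end_rule: trial_end      # or "speed_5pct"
  refine_onset: true
  common_frame: false

stats:
  level: trial             # or "subject"
  fdr_q: 0.05

classifier:
  comparison: [TD, ASD]
  hidden: [64, 32, 16]
  leaky_slope: 0.01
  lr_initial: 1.0e-5
  lr_reduced: 1.0e-6
  lr_switch_train_accuracy: 0.95
  epochs: 200
  batch_size: 32
  k: 10
  grouping: trial          # "subject" prevents same-subject leakage
  normalization: dataset   # "fold" avoids normalization leakage
  n_repeats: 20
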