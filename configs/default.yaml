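# Default pipeline configuration.  Every value marked "paper-unspecified"
# fills a gap the measurement protocol leaves open and is an explicit,
# auditable analysis choice.

preprocess:
  fir_cutoff: 5.0      # Hz — paper-unspecified; sit-to-stand energy < 3 Hz
  fir_order: 51        # taps — paper-unspecified
  ma_window: 0.25      # s — paper-unspecified

segmentation:
  min_prominence: 0.08        # g — paper-unspecified
  min_separation: 0.25        # s, same-type extrema — paper-unspecified
  amp_min: 0.08               # g — paper-unspecified
  transition_bounds: [0.2, 3.0]   # s — paper-unspecified physiological bounds
  cycle_bounds: [1.0, 12.0]       # s — paper-unspecified physiological bounds
  signal: gravity             # gravity-axis projection (alt: modulus)
  boundary_frac: 0.15         # fraction of extremum amplitude for timestamping

sampen:
  m: 2                 # template length (stated)
  r_factor: 0.2        # tolerance multiplier on series SD (stated)

selection:
  r_threshold: 0.90    # |r| above which one of a feature pair is dropped
  k_features: 7        # RFE target size, matching the named feature set
  rfe_estimator: linear
  interaction_top_k: 3

modeling:
  models: [rf, lr, svm, xgb, lgbm]
  folds: 5             # outer folds (stated)
  inner_folds: 3       # tuning folds — paper-unspecified
  seed: 0

feature_set: v1
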