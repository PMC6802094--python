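# Bundled demo study: 2 states, 3 impact PAs (TRs), 6 control PAs (WLSs).
# Every analysis threshold of the published design is visible here and
# overridable; runs are fully determined by `seed`.
seed: 42
simulation:
  n_states: 2
  n_tr: 3
  n_wls: 6
  scene_pixels: 32
  years: [1984, 2012]
  obs_per_year: 12
  cloud_fraction: 0.10
  water_fraction: 0.02
  noise_sd: 0.01
analysis:
  rainfall_window_mm: 500.0
  wls_min_area_km2: 75.0
  min_points_per_epoch: 5
  max_insufficient_fraction: 0.20
  robust_min_fraction: 0.20
  substantial_threshold_pct: 15.0
  declaration_year_in_after: true
  estimator: theil-sen
  distance_metric: boundary
  composite_timestamp: subset-mean
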