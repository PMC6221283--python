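# Two endemic taxa on opposite ends of a temperature/precipitation
# gradient, projected across three climate eras.
output_dir: runs/demo
master_seed: 11
background_n: 2000
R: 100
n_reps: 100
scenario:
  grid_rows: 80
  grid_cols: 80
  cell_size: 0.05
  origin: [-5.0, 38.0]
  autocorr_length: 8.0
  soil_fraction: 0.061
  soil_patch_scale: 6.0
  seed: 0
  era_shifts:
    # per-layer additive offsets: bio1, bio4, bio6, bio7, bio12, bio15, bio17
    lgm:          [-3.0, 0.5, -2.0, 1.0, 1.5, -0.5, 0.8]
    mid_holocene: [-1.0, 0.2, -0.7, 0.3, 0.5, -0.2, 0.3]
  taxa:
    tax_warm:
      n_occurrences: 60
      beta0: 0.0
      beta_linear:    [2.0, 0, 0, 0, -1.0, 0, 0.5]
      beta_quadratic: [-1.0, 0, 0, 0, 0, 0, 0]
    tax_cool:
      n_occurrences: 60
      beta0: 0.0
      beta_linear:    [-2.0, 0, 0, 0, 1.0, 0, -0.5]
      beta_quadratic: [-1.0, 0, 0, 0, 0, 0, 0]
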