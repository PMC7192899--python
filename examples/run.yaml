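# Worked example: landscape of the packaged gamma dose-response model.
# For experimental data replace `generator:` with e.g.
#   dataset: my_cells.csv
#   zero_input_value: 1.0   # remap uninduced (0-concentration) wells to x_min
design_space:
  x_min: 1.0
  x_max: 2048.0
  E_min: 2.0
  E_max: 1024.0
  sigma_min: 1.1
  sigma_max: 100.0
  n_E: 20
  n_sigma: 20
generator:
  kind: gamma
  noise_scale: 1.0
  support: {lo: 1.0, hi: 2048.0, n: 5}
  n_cells: 20000
srom:
  weight: 1.0
  moment_orders: [1, 2]
mi:
  n_bins: null            # default: ceil(sqrt(min group size)), capped at 256
  fractions: [1.0, 0.8, 0.625, 0.5]
  reps: 5
  bias_correction: true
output_dir: semil_out
seed: 1
plots: false
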