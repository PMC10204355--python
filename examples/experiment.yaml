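# The desk-scale bias-type x level x model grid with 3 repetitions.
grid:
  bias_types: [random, false_positive, false_negative]
  levels: [0.0, 0.10, 0.25]
  models: [baseline, improved]
  n_repetitions: 3
  base_seed: 42
  clean_val: true
model:
  backbone: small_cnn
  input_side_px: 32
loss:
  alpha: 1.0
  horizontal_flip_p: 0.5
  vertical_flip_p: 0.5
train:
  lr: 0.001
  max_epochs: 30
  batch_size: 32
  patience: 5
  alpha_grid: [1.0]
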