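# Desk-scale synthetic dataset: 200/class train, 50/class val, 100+100 test.
dataset:
  n_train_per_class: 200
  n_val_per_class: 50
  n_test: [100, 100]
  seed: 7
image:
  side_px: 32
  background_level: 0.3
  noise_sd: 0.10
  n_blobs_range: [1, 3]
  blob_amplitude: 0.12
  blob_sigma_px: 3.0
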