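# Desk-scale recipe: runs end-to-end on one CPU in minutes.
seed: 0
catalog:
  n_hues: 10
  n_values: 4
  n_chromas: 4
  spacing_target: 7.3
illuminants:
  n_dseries: 5
  n_jittered: 35
  spread_target: 8.55
  test_distance: 10.0
scenes:
  image_size: [32, 32]
  images_per_cell: 2        # CC: two images per (class, illuminant)
  d65_images_per_cell: 40   # D65-only variant (no illumination dimension)
model:
  width_scale: 0.5
  dropout_rate: 0.2         # reduced from 0.4: desk scale underfits
training:
  epochs: 45
  lr: 0.002
  lr_decay_every: 15
  batch_size: 128
  n_instances: 3
evaluation:
  replicates: 10
  conditions: [normal, no_patch, wrong_background]
  baseline_replicates: 2
rsa:
  taps: [conv1, conv2, conv3, fc1, fc2]
  reference: munsell
  include_random_control: true
  replicates: 2
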