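# Full-scale recipe: the measured-chip-set regime (40x8x8 grid, 279
# illuminants, 128x128 images, 90 epochs, 10 instances). Config-complete,
# but training at this scale is GPU-class work; the desk_default recipe is
# the supported CPU path.
seed: 0
catalog:
  n_hues: 40
  n_values: 8
  n_chromas: 8
  spacing_target: 7.3
illuminants:
  n_dseries: 43
  n_jittered: 236
  spread_target: 8.55
  test_distance: 10.0
scenes:
  image_size: [128, 128]
  images_per_cell: 1
  d65_images_per_cell: 279
model:
  width_scale: 1.0
training:
  epochs: 90
  lr: 0.001
  lr_decay_every: 30
  batch_size: 800
  n_instances: 10
evaluation:
  replicates: 10
  conditions: [normal, no_patch, wrong_patch, wrong_background]
  baseline_replicates: 10
rsa:
  taps: [conv1, conv2, conv3, fc1, fc2]
  reference: munsell
  include_random_control: true
  replicates: 10
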