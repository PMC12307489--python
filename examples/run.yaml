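# Desk-scale run configuration: synthetic 4-class ERD sessions at 50 Hz
# and a scaled-down HA-FuseNet that trains on one CPU.
synth:
  n_subjects: 9
  n_trials_per_class: 20        # 80 trials per subject
  sampling_rate: 50.0
  n_channels: 22
  noise_sd: 0.5                 # microvolts, 1/f background
  rhythm_amplitude: 2.0         # microvolts, ongoing mu/beta rhythms
  subject_shift_sd: 0.2
  class_profiles:               # per class: channel -> [center Hz, bandwidth Hz, attenuation]
    - {11: [10.0, 2.0, 0.3], 16: [18.0, 4.0, 0.3]}   # left hand
    - {7:  [10.0, 2.0, 0.3], 13: [18.0, 4.0, 0.3]}   # right hand
    - {9:  [10.0, 2.0, 0.3], 2:  [18.0, 4.0, 0.3]}   # feet
    - {5:  [10.0, 2.0, 0.3], 18: [18.0, 4.0, 0.3]}   # tongue

disnet:
  n_channels: 22
  n_times: 150                  # 3 s at 50 Hz
  stem_depth: 4
  stem_kernel: 7
  bottleneck_expansion: 2
  bottleneck_kernel: 9
  branch_kernels: [5, 9]        # 100 / 180 ms at 50 Hz
  branch_depth: 4
  pool_size: 150                # global average pooling over the trial
  dropout: 0.25

lsnet:
  n_layers: 2
  hidden: 48
  time_pool: 5

fusion:
  target_depth: 8
  kernel: 5

train:
  batch_size: 32
  epochs: 40
  learning_rate: 1.0e-3
  weight_decay: 5.0e-3
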