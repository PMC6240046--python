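workdir: demo_run
n_subjects: 6
grid_shape:
- 12
- 12
- 12
protocol:
  n_cue_sounds: 25
  cue_repetitions: 2
  n_control_sounds: 5
  control_repetitions: 5
  sound_duration: 0.5
  model_duration: 5.0
  isi_range:
  - 4.0
  - 8.0
  block_size: 5
  tr: 2.511
  n_scans: null
  start_offset: 10.0
truth:
  n_parcels: 115
  n_modules: 5
  parcel_module:
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 4
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  - 5
  seed_parcel: 1
  within_module_r: 0.6
  between_module_r: 0.1
  seed_cross_boost: 0.25
  amplitude_mean: 1.0
  noise_sd: 0.3
  ar1_rho: 0.3
  voxel_amp_sd: 0.1
effect:
  error_mean: 2.74
  item_sd: 0.85
  subject_sd: 0.5
  forgetting_mean: 0.37
  forgetting_sd: 0.25
  item_noise_sd: 1.0
  coupling: -2.5
  uncued_weight: 0.6
  n_items: 50
pc_effect_range:
- 0.0
- 0.5
q: 0.05
z_threshold: 2.33
gamma: 1.0
n_restarts: 100
n_perm: 1000
ar1: estimate
seed: 7
seeds: {}
verbosity: INFO
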