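beta_bins:
- - 50.0
  - 150.0
- - 150.0
  - 250.0
- - 250.0
  - 500.0
emg_bins:
- - 75.0
  - 200.0
- - 200.0
  - 300.0
- - 300.0
  - 500.0
emg_is_envelope: true
epoch:
- -400.0
- 1400.0
fit:
  mu_k: 1.0e-06
  mu_m: 1.0
  mu_s: 1000.0
  n_starts: 3
  window:
  - 0.0
  - 1300.0
fs: 1000.0
generator_variant: hSRM-kin-a2
log_level: INFO
magnitudes:
- small
- medium
- large
n_participants: 3
noise:
  sigma0: 0.01
  sigma_prop: 0.05
plant:
  damping: 6.0
  effective_stiffness: 20.0
seed: 0
trials_per_cell: 2
variants:
- mSRM
- hSRM-kin
- hSRM-kin-a2
- hSRM-N1
- hSRM-beta
- cSRM-N1
- cSRM-N1-a1
- cSRM-beta
- cSRM-beta-a1
write_trials: false
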