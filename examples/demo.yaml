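# Planted-cohort demonstration: one modulated-occurrence state, one
# modulated-duration state, a circadian and a 10.6-day multidien cycle.
outdir: runs/demo
seed: 901
patient: synthetic-01
stages: [simulate, states, cycles, associate]
synth:
  n_channels: 5
  n_seizures: 300
  recording_days: 90
  state_library_size: 4
  multidien_periods: [10.6]
  seizure_phase_kappa: 1.0
  seizure_phase_mu: 1.5707963267948966   # pi/2, rising phase
  occurrence_mod_base_prob: 0.02
  occurrence_mod_amplitude: 0.25
  occurrence_mod: [[0, 1, 3.0, 1.5707963267948966]]
  duration_mod: [[1, 1, 0.8]]
rank_range: [2, 8]
n_repeats: 10
n_perm: 10000
alpha: 0.05
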