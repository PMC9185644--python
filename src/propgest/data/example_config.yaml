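# Example run configuration (all keys optional; defaults shown).
mode: two-sensor     # or three-sensor
w: 30                # window size, samples
s: 5                 # training window step, samples
seed: 0              # root seed for every stage
n_subjects: 8        # simulated subjects (one choreography each)
n_trials: 10         # repeats per subject
n_eval_trials: 3     # held-out choreographies for end-to-end evaluation
noise_sd: 0.35       # simulator accelerometer noise, m/s^2
filter_order: 2      # Butterworth order (frequency features)
filter_cutoff_hz: 4.0
fs_hz: 30.0
n_folds: 10
nf_max: 30
side_algos:          # algorithm families searched per side
  left: [svm]
  right: [random_forest]
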