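# Configuration for `ratvision fit-csf --config examples/csf.yaml`.
# Omit target_csv to fit the built-in rodent CSF stand-in.
sigma_blur_grid: [0.5, 1.0, 2.0, 4.0, 8.0]
sigma_noise_grid: [0.05, 0.1, 0.2, 0.3, 0.45]
patch_grid: [28]
peak_sensitivity: 20.0
n_per_class: 500
n_trials: 80
n_reps: 1
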