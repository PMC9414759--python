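n_subjects: 2
human_trials: 1
dummy_trials: 1
master_seed: 5
architectures: [cnn1d]
losses: [mae]
max_epochs: 2
patience: 2
outdir: tiny_run
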