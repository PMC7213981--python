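# Luminescence-decay simulation and Hill fit defaults.
t05: 120.0          # min
n_hill: 2.0
bg: 0.1
t_max: 480.0        # min
n_timepoints: 17
n_replicates: 3
noise_sd: 0.05
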