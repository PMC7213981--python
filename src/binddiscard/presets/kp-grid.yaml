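# Phosphorylation-rate estimation grid: invert the measured normalized slope
# over plausible NICD abundances and basal degradation rates.
slope_normalized: -0.0294
N_e: 5.4
Gamma_p: 1/8
NICD0_range: {min: 100, max: 10000, num: 50, spacing: log}
Gamma_up_range: {min: 1/1000, max: 1/30, num: 50, spacing: log}
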