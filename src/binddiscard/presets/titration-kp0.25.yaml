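# Steady-state titration, slow phosphorylation rate.
params:
  NICD0: 2000
  Gamma_up: 1/120
  Gamma_p: 1/8
  k_p: 0.25
  k_alpha: 1.0
  N_e: 0.0
ns_values: [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 24, 28, 32, 36]
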