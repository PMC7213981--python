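# Steady-state titration of nuclear NICD against synthetic SPS number,
# fast phosphorylation variant.
params:
  NICD0: 2000
  Gamma_up: 1/120   # min^-1; basal half-life ~120 min (half-life = 1/Gamma)
  Gamma_p: 1/8      # min^-1; phosphorylated NICD decays much faster
  k_p: 1.0          # min^-1
  k_alpha: 1.0      # molecules/nucleus; strong-binding regime
  N_e: 0.0
ns_values: [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 24, 28, 32, 36]
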