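# Signal-duration sensitivity: wild type vs production heterozygote (NICD0
# halved) vs 12 added synthetic SPS sites, from empty nuclei at signal onset.
params:
  NICD0: 2000
  Gamma_up: 1/120
  Gamma_p: 1/8
  k_p: 0.0          # derived from slope_normalized at run time
  k_alpha: 1.0
  N_e: 5.4
slope_normalized: -0.0294
Ns_transgene: 12
t_short: 10.0       # min; a short-pulse tissue (e.g. bristle precursor choice)
t_long: 100000.0    # min; effectively steady state (margin maintenance)
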