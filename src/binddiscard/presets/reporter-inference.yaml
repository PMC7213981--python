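# Reporter-titration inference conditions: wild type vs a Cdk8-kinase-module
# heterozygote whose phosphorylation rate is halved.  k_p is not stored: it is
# re-derived at run time from the measured normalized slope via the closed-form
# inversion, so the preset mirrors the calibration, not its result.
params:
  NICD0: 2000
  Gamma_up: 1/120
  Gamma_p: 1/8
  k_p: 0.0          # placeholder; derived from slope_normalized at run time
  k_alpha: 1.0
  N_e: 5.4
slope_normalized: -0.0294   # measured per-site slope of the normalized reporter curve
kp_het_factor: 0.5          # heterozygote phosphorylation rate relative to wild type
ns_values: [0, 6, 12, 18]
points_used_reference: [0, 6, 12]      # largest reference point is saturated
points_used_mutant: [0, 6, 12, 18]
n_discs: 8
noise_cv: 0.15
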