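# binddiscard

Quantitative modeling and inference for **binding-site-coupled degradation of
the Notch intracellular domain (NICD)** — the "bind and discard" mechanism in
which enhancers carrying Su(H)-paired sites (SPS) act as degradation drains:
NICD complexes bound at such sites are phosphorylated by the Cdk8 kinase
module of Mediator and routed to fast proteasomal turnover, lowering nuclear
NICD and Notch-dependent transcription everywhere else in the nucleus.

The package is aimed at quantitative/systems biologists who want to

- solve the kinetic model of nuclear NICD titration by SPS "drain" sites
  (steady states, time courses, titration curves, parameter sweeps);
- analyse reporter-titration experiments (fluorescence vs synthetic-site
  number in two genotypes) to extract the slope ratio, the effective number
  of endogenous SPS-equivalent sites `Ne`, and the per-site phosphorylation
  rate `kp`;
- fit half-lives of luminescence decay curves with a decreasing Hill
  function;
- validate the mean-field model against an exact event-driven stochastic
  simulation; and
- generate synthetic datasets with the statistical structure of the real
  assays, so the whole pipeline is testable end to end.

## The model

NICD enters the nucleus at constant rate `P_NICD` and is degraded at rate
`Γup` when unphosphorylated and unbound (define `NICD0 = P_NICD/Γup`, the
baseline steady-state abundance; throughout, half-life is `1/Γ`). With
`N = Ne + Ns` identical, independent SPS sites, the equilibrium occupancy of
a single site follows the partition function

```
Z = 1 + αup + αp,   αup = NICDup/kα,   αp = NICDp/kα,
p_up = αup/Z,  p_p = αp/Z
```

with `kα` the dissociation constant of the NICD/CSL/Mastermind–SPS
interaction. Bound unphosphorylated NICD is phosphorylated at rate `kp` and
phosphorylated NICD, once released, decays at `Γp ≫ Γup`. In units of `Γup`
(primes), the steady state solves

```
0 = NICD0 − NICDup − N·p_up·(kp′ − 1)
0 = N·p_up·kp′ − (NICDp − N·p_p)·Γp′
```

For few sites and `kp ≫ Γup`, total NICD falls linearly with site number:

```
NICDtot ≈ NICD0 − (Ne + Ns)·kp′·(1 − 1/Γp′),   slope ∝ kp
```

so halving `kp` (a Cdk8-kinase-module heterozygote) halves the slope — the
basis of the slope-ratio test — and the wild-type and mutant lines cross at
`Ns = −Ne`. Inverting the normalized slope `s` gives the closed form

```
kp = NICD0·Γup / ((Ne − 1/s)·(1 − Γup/Γp))
```

Decay curves are fitted with the decreasing Hill function
`f(t) = (t05^n + bg·t^n)/(t05^n + t^n)`.

## Worked example

```python
import binddiscard as bd

# phosphorylation rate implied by the measured normalized slope -0.0294/site
kp = bd.estimate_kp_from_slope(-0.0294, NICD0=2000, Gamma_up=1/120,
                               Gamma_p=1/8, N_e=5.4)          # 0.453 /min

wt = bd.KineticParams(NICD0=2000, Gamma_up=1/120, Gamma_p=1/8,
                      k_p=kp, N_e=5.4)
print(bd.titration_curve(wt, [0, 6, 12, 18]))

# a full synthetic experiment pushed through the inference pipeline
ds = bd.gen_reporter_dataset(bd.default_reporter_spec(seed=1))
out = bd.analyze_reporter(ds, [0, 6, 12], [0, 6, 12, 18],
                          NICD0=2000, Gamma_up=1/120, Gamma_p=1/8)

fit = bd.fit_hill_decay(bd.gen_decay_curves(bd.default_decay_spec(seed=1)),
                        seed=0)

d = bd.duration_sensitivity(wt, Ns_transgene=12, t_short=10, t_long=1e5)
```

prints (steady-state titration of total nuclear NICD):

```
 n_sites     nicd_up    nicd_p    nicd_tot  nicd_tot_norm
       0 1715.198126 19.402928 1734.601054       1.000000
       6 1408.988970 40.456991 1449.445961       0.835608
      12 1119.857096 60.669105 1180.526201       0.680575
      18  858.289939 79.522305  937.812243       0.540650
```

and the downstream estimates for this seed:

```
slope ratio 1.84 +/- 0.47  (95% CI 0.02..3.66)     # true value 2
Ne 4.4 +/- 4.7                                     # true value 5.4
kp 0.438 /min                                      # true value 0.453
t05 111.5 min (95% CI 102.3..120.6)                # true value 120
reductions at 10 min:       sites 6.1%, halved production 51.6%
reductions at steady state: sites 31.9%, halved production 57.4%
```

The last two lines are the signal-duration story: extra drain sites barely
dent NICD during a short signaling pulse but cut it by a third at steady
state, whereas halving production hurts at all durations — which is why
long-duration tissues (wing margin) are sensitive to drain sites while
short-pulse tissues (bristle precursor selection) are not.

The same stages are available from the shell:

```
binddiscard steady --preset titration-kp1.0 --out titration.csv
binddiscard synth --kind reporter --seed 5 --outdir data/
binddiscard fit-reporter data/reporter.csv --out result.json
binddiscard fit-decay data/decay.csv --out decay.json
binddiscard kp-grid --out grid.csv
binddiscard dynamics --preset duration-default --outdir traj/
```

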