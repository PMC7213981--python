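# Methods

## Model and assumptions

The package models the nuclear pool of the Notch intracellular domain
(NICD) in a single nucleus, in molecules per nucleus and minutes. Four
species make up the full reaction network: unphosphorylated/phosphorylated
× bound/unbound NICD. NICD enters at constant rate `P_NICD`; unbound
unphosphorylated NICD decays at `Γup`, unbound phosphorylated NICD at
`Γp ≫ Γup`; NICD complexes bind SPS sites with dissociation constant
`kα = k_off/k_on`; bound unphosphorylated NICD is phosphorylated at `kp`
by the Cdk8 kinase module recruited to the site. Bound NICD is protected
from degradation (the `kp′ − 1` sequestration term in the steady-state
equations).

The deterministic module reduces this to two slow variables (total
unphosphorylated and total phosphorylated NICD) under three assumptions,
each of which the stochastic oracle can probe:

1. **Fast binding.** Site binding equilibrates much faster than
   production/degradation/phosphorylation, so occupancy follows the
   single-site partition function `Z = 1 + NICDup/kα + NICDp/kα`.
2. **Molecules ≫ sites.** Copy numbers (10²–10⁴) dwarf the site count
   (≤ ~36), so the statistical weights use total rather than free
   concentrations and mean-field factorization is accurate.
3. **Independent sites.** The `N = Ne + Ns` sites bind independently;
   `Ne` is a real-valued *effective* count summarizing the genome's many
   weaker endogenous sites in units of one strong synthetic SPS, `Ns` an
   integer transgene count.

No dephosphorylation, no spatial structure, no cis-inhibition, and no
transcription model downstream of NICD.

## Parameters, units, conventions

| parameter | meaning | default / central value |
|---|---|---|
| `NICD0 = P_NICD/Γup` | baseline abundance | 2000 molecules/nucleus |
| `Γup` | basal degradation rate | 1/120 min⁻¹ |
| `Γp` | phosphorylated degradation rate | 1/8 min⁻¹ |
| `kp` | site-coupled phosphorylation rate | derived from the slope (≈0.45 min⁻¹) |
| `kα` | site dissociation constant | 1 molecule/nucleus |
| `Ne` | effective endogenous sites | 5.4 |
| `Ns` | synthetic sites | 0–18 (36 max sweep) |

- **Half-life convention**: half-life `= 1/Γ` (not `ln2/Γ`); `Γup = 1/120`
  is described as a "120-minute half-life". This matches the pairing used
  in the turnover estimates the defaults are drawn from.
- **Time scaling**: the two-variable dynamic system is dimensionless in
  time (units of `1/Γup`) in its raw form; the integrator multiplies the
  right-hand sides by `Γup` to work in physical minutes. A
  `dimensionless_time` mode exposes the raw scaling for cross-checks.
- **`kα` default = 1 molecule/nucleus everywhere.** Steady-state results
  are insensitive to `kα` in the strong-binding regime (`NICDtot ≫ kα`),
  which is the regime the analysis assumes. We deliberately use the same
  strong-binding default for the duration-sensitivity analyses: a large
  `kα` (say 10³) silently exits strong binding for low-abundance parameter
  variants (`NICD0 = 200`), leaving sites unoccupied and erasing the
  steady-state site effect the robustness sweep is supposed to exhibit.
  `kα` is configurable on every entry point.
- **Calibration**: `kp` is never hard-coded; wherever a preset needs it,
  it is re-derived at run time from the measured normalized slope
  (−0.0294 per site) via the closed-form inversion, under that preset's
  own `NICD0`, `Γup`, `Γp` (this is also how each robustness variant gets
  its `kp`).

## Numerical choices

- **Steady state**: `scipy.optimize.root` (Powell hybrid) with an analytic
  Jacobian, multistart from `(NICD0, ~0)`, `(NICD0/2, NICD0/10)` and
  `(~0, ~0)`; roots accepted when the max residual is below
  `1e-10 · NICD0` and pools are ≥ −1e-9 (clipped to 0). `N = 0` is handled
  in closed form.
- **Dynamics**: LSODA (stiff-capable), `rtol 1e-8`,
  `atol 1e-10·max(NICD0, 1)`, initial condition `(0, 0)` = signal onset
  into an empty nucleus. Long-time integration agrees with the algebraic
  steady state to 1e-6 relative across a 27-point grid (tested).
- **Linear regime**: `linear_regime` returns the `kp ≫ Γup` forms
  (slope `−kp′(1 − 1/Γp′)`); the validity flag requires the total site
  load `(Ne+Ns)·kp′·(1 − 1/Γp′) ≤ 0.3·NICD0` — inside that envelope the
  closed form tracks the full solution to better than 5% (tested). The
  flag `approximation_ok` warns when `Γp′ ≤ 1`.
- **Initial titration slope**: where a "slope proportional to `kp`" is
  measured from the nonlinear curve, the *initial finite difference*
  `NICDtot(1) − NICDtot(0)` is used. Secants over wider spans fold in
  curvature and understate the ratio.
- **kp inversion**: `kp = NICD0·Γup/((Ne − 1/s)(1 − Γup/Γp))` with
  `s ≤ 0`; `s = 0` maps to `kp = 0`; a non-positive denominator (possible
  only for invalid inputs such as `Γup ≥ Γp`) raises a domain error, and
  grid cells inherit it as NaN masks.
- **Hill-decay fit**: pooled (all replicates stacked) nonlinear least
  squares with bounds `t05 > 0`, `n ∈ (0, 10]`, `bg ∈ [0, 1)`;
  initialization `bg₀ = min(value)`, `t05₀` = time of the value nearest
  `(1+bg₀)/2`, `n₀ = 2`. Confidence intervals by a seeded bootstrap over
  replicate curves (residual resampling for a single replicate), 1000
  resamples by default; a linearised-covariance interval is available.

## Inference pipeline

Per-disc reporter values are normalized by the reference-genotype
zero-site mean (one shared constant, so intercepts stay comparable;
idempotent). Each genotype is fitted by *unweighted OLS on per-condition
means* — one point per site count — mirroring how such reporter series are
analysed in practice; an SEM-weighted option exists but is off by default.
Defaults use reference points {0, 6, 12} (the largest reference condition
sits in the saturated regime) and mutant points {0, 6, 12, 18}.

The slope ratio is reference/mutant with first-order delta-method error,
fits treated as independent:
`var(r) = var(s_ref)/s_mut² + s_ref²·var(s_mut)/s_mut⁴`.

**95% interval of the ratio.** The default interval uses a Student-t
quantile at the Satterthwaite effective degrees of freedom of the two
variance components. With 3 and 4 regression points the residual variances
carry only 1 and 2 degrees of freedom, and a plain `±1.96·se` interval
demonstrably under-covers (measured ≈86% instead of 95% over 200
simulated experiments at the default design; the t interval restores
≈95%). `ci_method="z"` gives the normal-quantile interval for comparison.
The reported `se` itself is identical under both.

`Ne` is minus the crossing abscissa of the two fitted lines,
`x* = (b_mut − b_ref)/(s_ref − s_mut)`, with the delta method over all
four fit parameters. `kp` is then the closed-form inversion evaluated at
the fitted reference slope and estimated `Ne`; when a noisy dataset yields
a negative `Ne` the pipeline reports the inversion as unavailable rather
than extrapolating to a meaningless rate.

## Stochastic oracle

Direct-method (Gillespie) simulation of the full 8-reaction network with
discrete sites and molecules, compiled with numba when available. State is
recorded on a fixed grid (value just before the first jump past each grid
time); the stationary mean of `NICDtot` is reported with a batch-means
standard error (burn-in `10/Γup`, up to 20 batches). The validation
conditions use `kα = 1000` via `k_on = 0.3`, `k_off = 300`: binding must
be genuinely fast relative to *all* other rates — at `k_off = 10` the
quasi-equilibrium error of order `kp/k_off` (≈5%) produces a visible ~2%
bias in mean NICD, while at `k_off = 300` the residual bias is well below
the Monte-Carlo error of a 2×10⁵-minute run. Site conservation is
structural and additionally guarded in the kernel.

## Synthetic data

- **Reporter generator**: per-disc value = gain × steady-state `NICDtot`
  for that genotype/site count × lognormal noise with unit mean and CV
  0.15 (the per-disc CV is not tabulated for the real assay; 0.15 is a
  realistic imaging-variability figure and is a free parameter). Eight
  discs per condition, site counts {0, 6, 12, 18}, mutant `kp` = half of
  reference. Fluorescence is assumed proportional to NICD (a saturating
  readout option exists, off by default); the readout reporter's own six
  sites are considered part of the `Ne` baseline, not counted in `Ns`.
- **Decay generator**: Hill curve plus additive Gaussian noise (sd 0.05),
  17 timepoints over 0–480 min, 3 replicates, each replicate re-normalized
  to its own t=0 reading (as plate assays are). Note this re-normalization
  injects a correlated scale error of order the noise sd into every later
  timepoint, which is why single-curve half-life errors of ~5% are
  expected even though the mean bias stays below 3%.

Passing recovery tests on these generators shows the pipeline is unbiased
and correctly calibrated *under the generator's assumptions*; it cannot
rule out biases from features the generators omit (saturating readouts,
spatial heterogeneity, batch effects).

## Known limitations

- `Ne` enters as a single effective number; heterogeneous endogenous site
  strengths, cooperativity between cassettes, or avidity effects of
  clustered sites are not modeled.
- The heterozygote models are idealized: halved production for a receptor
  heterozygote, exactly halved `kp` for a kinase-module heterozygote (no
  dosage compensation).
- The delta-method errors assume independent genotype fits; the shared
  normalization constant induces a small correlation that is ignored (it
  cancels exactly in the ratio).
- The ratio estimator is heavy-tailed when the mutant slope is near zero;
  point estimates far from 2 and very wide bootstrap intervals are
  expected in a minority of simulated experiments at the default noise.
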