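"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* reporter titrations — per-disc fluorescence means for two genotypes
  (reference, and a mutant with reduced site-coupled phosphorylation) across
  synthetic-site counts, equal to the model's steady-state NICD_tot times a
  reporter gain, under multiplicative lognormal disc-to-disc noise;
* luminescence decay curves — Hill-decay values plus additive Gaussian noise,
  re-normalized per replicate to 1 at t=0 as the assay does.

Ground truth (expectations, linear-regime slopes, Ne, phosphorylation rates)
travels with each dataset so recovery tests can close the loop.

What these generators do NOT emulate: spatial structure within a disc,
reporter maturation/saturation kinetics (a saturating readout is available
but off by default), day effects or plate effects, and any coupling between
noise and site count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .decay import DecayCurve, hill_decay
from .inference import MUTANT, REFERENCE, ReporterDataset
from .params import KineticParams, ParameterError, load_preset

__all__ = [
    "ReporterSimSpec",
    "DecaySimSpec",
    "gen_reporter_dataset",
    "gen_decay_curves",
    "default_reporter_spec",
    "default_decay_spec",
]


@dataclass(frozen=True)
class ReporterSimSpec:
    """Design of a simulated reporter-titration experiment."""

    params_ref: KineticParams
    params_mut: KineticParams
    seed: int
    ns_values: tuple = (0, 6, 12, 18)
    n_discs: int = 8
    noise_cv: float = 0.15  # disc-to-disc coefficient of variation
    reporter_gain: float = 1.0  # fluorescence a.u. per molecule
    saturating_readout: bool = False
    readout_k: float = float("nan")  # half-saturation (molecules) when saturating

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.n_discs < 2:
            raise ParameterError("n_discs must be >= 2")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.saturating_readout and not self.readout_k > 0:
            raise ParameterError("saturating readout needs readout_k > 0")


def default_reporter_spec(seed: int, **overrides) -> ReporterSimSpec:
    """Study-design defaults: the packaged reporter-inference conditions.

    The reference phosphorylation rate is derived from the preset's measured
    normalized slope by the closed-form inversion; the mutant rate is the
    preset's heterozygote fraction (one half) of it.
    """
    cfg = load_preset("reporter-inference")
    p = dict(cfg["params"])
    kp = core.estimate_kp_from_slope(
        cfg["slope_normalized"], p["NICD0"], p["Gamma_up"], p["Gamma_p"], p["N_e"]
    )
    ref = KineticParams(**{**p, "k_p": kp})
    mut = ref.replace(k_p=kp * cfg["kp_het_factor"])
    spec = dict(
        params_ref=ref,
        params_mut=mut,
        seed=seed,
        ns_values=tuple(cfg["ns_values"]),
        n_discs=cfg["n_discs"],
        noise_cv=cfg["noise_cv"],
    )
    spec.update(overrides)
    return ReporterSimSpec(**spec)


def _readout(spec: ReporterSimSpec, nicd_tot: float) -> float:
    if spec.saturating_readout:
        return spec.reporter_gain * nicd_tot / (spec.readout_k + nicd_tot)
    return spec.reporter_gain * nicd_tot


def gen_reporter_dataset(spec: ReporterSimSpec) -> ReporterDataset:
    """Simulate per-disc reporter values for both genotypes.

    Per-disc value = readout(steady-state NICD_tot) x lognormal noise with
    the requested CV and unit mean.  Reproducible given ``spec.seed``.  The
    returned dataset carries a ``truth`` dict (expectations per condition,
    exact linear-regime slopes, Ne, and the two phosphorylation rates).
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    rows = []
    truth_exp = {}
    for genotype, params in ((REFERENCE, spec.params_ref), (MUTANT, spec.params_mut)):
        for ns in spec.ns_values:
            try:
                ss = core.steady_state(params.replace(N_s=int(ns)))
            except Exception as exc:
                raise RuntimeError(
                    f"steady state failed for genotype={genotype}, n_sites={ns}: {exc}"
                ) from exc
            expect = _readout(spec, ss.NICD_tot)
            truth_exp[(genotype, int(ns))] = expect
            if spec.noise_cv > 0:
                noise = rng.lognormal(-(sigma**2) / 2.0, sigma, spec.n_discs)
            else:
                noise = np.ones(spec.n_discs)
            for d in range(spec.n_discs):
                rows.append((genotype, int(ns), f"{genotype}_{ns}_{d}", expect * noise[d]))
    df = pd.DataFrame(rows, columns=["genotype", "n_sites", "disc_id", "value"])
    ds = ReporterDataset(data=df)
    lr_ref = core.linear_regime(spec.params_ref)
    lr_mut = core.linear_regime(spec.params_mut)
    truth = {
        "expectations": truth_exp,
        "slope_normalized_ref": lr_ref.slope_normalized,
        "slope_normalized_mut": lr_mut.slope_normalized,
        "ratio": spec.params_ref.k_p / spec.params_mut.k_p
        if spec.params_mut.k_p
        else float("inf"),
        "N_e": spec.params_ref.N_e,
        "k_p_ref": spec.params_ref.k_p,
        "k_p_mut": spec.params_mut.k_p,
        "seed": spec.seed,
    }
    object.__setattr__(ds, "truth", truth)
    return ds


@dataclass(frozen=True)
class DecaySimSpec:
    """Design of a simulated luminescence-decay experiment."""

    seed: int
    t05: float = 120.0
    n_hill: float = 2.0
    bg: float = 0.1
    t_max: float = 480.0
    n_timepoints: int = 17
    n_replicates: int = 3
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if not self.t05 > 0 or not self.n_hill > 0 or not 0 <= self.bg < 1:
            raise ParameterError("t05 > 0, n_hill > 0 and bg in [0,1) required")
        if self.n_timepoints < 4 or self.n_replicates < 1:
            raise ParameterError("need >= 4 timepoints and >= 1 replicate")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def default_decay_spec(seed: int, **overrides) -> DecaySimSpec:
    cfg = load_preset("decay-default")
    spec = dict(
        seed=seed,
        t05=cfg["t05"],
        n_hill=cfg["n_hill"],
        bg=cfg["bg"],
        t_max=cfg["t_max"],
        n_timepoints=cfg["n_timepoints"],
        n_replicates=cfg["n_replicates"],
        noise_sd=cfg["noise_sd"],
    )
    spec.update(overrides)
    return DecaySimSpec(**spec)


def gen_decay_curves(spec: DecaySimSpec) -> DecayCurve:
    """Simulate replicate decay wells.

    Values are the Hill curve plus additive Gaussian noise, then each
    replicate is divided by its own t=0 reading (as the assay normalizes per
    well), which pins the first value to 1 exactly.  The returned curve
    carries a ``truth`` dict with the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_max, spec.n_timepoints)
    clean = hill_decay(t, spec.t05, spec.n_hill, spec.bg)
    rows = []
    for r in range(spec.n_replicates):
        v = clean + rng.normal(0.0, spec.noise_sd, len(t)) if spec.noise_sd else clean.copy()
        v = v / v[0]
        for ti, vi in zip(t, v):
            rows.append((ti, f"rep{r}", vi))
    curve = DecayCurve(data=pd.DataFrame(rows, columns=["time_min", "replicate", "value"]))
    object.__setattr__(
        curve,
        "truth",
        {"t05": spec.t05, "n_hill": spec.n_hill, "bg": spec.bg, "seed": spec.seed},
    )
    return curve
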