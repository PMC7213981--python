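"""Reporter-titration analysis: normalization, regression, slope ratio, Ne.

The experimental design: a fluorescent Notch-activity reporter is read out
per imaginal disc while the number of synthetic SPS "drain" sites is varied
(0, 6, 12, 18) in two genotypes — a reference (wild type) and a mutant whose
site-coupled phosphorylation rate is reduced (a Cdk8-kinase-module
heterozygote, nominally halved).  In the model's linear regime the reporter
falls linearly with site number with slope proportional to the
phosphorylation rate, so the reference/mutant slope ratio estimates the
fold-change in phosphorylation activity, and the abscissa where the two
fitted lines cross estimates (minus) the effective number of endogenous
SPS-equivalent sites, Ne.

Fits are ordinary least squares on per-condition means (one point per site
count), mirroring the experimental analysis; fit errors are propagated to
the ratio and crossing point by the first-order delta method, with the two
genotype fits treated as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .params import ParameterError

__all__ = [
    "ReporterDataset",
    "LineFit",
    "SlopeRatioEstimate",
    "NeEstimate",
    "normalize",
    "fit_line",
    "slope_ratio",
    "estimate_ne",
    "infer_kp",
    "analyze_reporter",
]

REFERENCE = "reference"
MUTANT = "mutant"

_COLUMNS = ["genotype", "n_sites", "disc_id", "value"]


@dataclass(frozen=True)
class ReporterDataset:
    """Per-disc reporter fluorescence across genotypes and site counts.

    ``data`` has columns ``genotype`` (``reference`` / ``mutant``),
    ``n_sites``, ``disc_id`` and ``value`` (arbitrary fluorescence units).
    """

    data: pd.DataFrame
    normalized: bool = False
    normalization_constant: float = float("nan")

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ParameterError(f"reporter table missing columns {missing}")
        if (self.data["n_sites"] < 0).any():
            raise ParameterError("n_sites must be >= 0")
        if self.data.groupby(["genotype", "n_sites"]).size().min() < 1:
            raise ParameterError("every (genotype, n_sites) group must be non-empty")

    def condition_means(self, genotype: str) -> pd.Series:
        sub = self.data[self.data["genotype"] == genotype]
        if sub.empty:
            raise ParameterError(f"no rows for genotype {genotype!r}")
        return sub.groupby("n_sites")["value"].mean()

    @classmethod
    def from_csv(cls, path) -> "ReporterDataset":
        return cls(data=pd.read_csv(path)[_COLUMNS])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def normalize(ds: ReporterDataset) -> ReporterDataset:
    """Divide every value by the reference-genotype zero-site mean.

    Both genotypes share the single constant, so fitted intercepts remain
    comparable; idempotent (normalizing twice changes nothing).
    """
    if ds.normalized:
        return ds
    ref0 = ds.data[(ds.data["genotype"] == REFERENCE) & (ds.data["n_sites"] == 0)]
    if ref0.empty:
        raise ParameterError("missing reference-genotype n_sites=0 baseline group")
    c = float(ref0["value"].mean())
    if not (math.isfinite(c) and c > 0):
        raise ParameterError(f"baseline mean must be positive, got {c}")
    out = ds.data.copy()
    out["value"] = out["value"] / c
    nds = ReporterDataset(data=out, normalized=True, normalization_constant=c)
    if hasattr(ds, "truth"):  # carry simulation ground truth through
        object.__setattr__(nds, "truth", ds.truth)
    return nds


@dataclass(frozen=True)
class LineFit:
    """OLS line through per-condition means of one genotype."""

    slope: float
    intercept: float
    covariance: np.ndarray  # 2x2, order (intercept, slope)
    n_points: int
    points_used: tuple
    dof: int  # residual degrees of freedom (0 when n_points == 2)


def fit_line(ds: ReporterDataset, genotype: str, points_used=None) -> LineFit:
    """Unweighted OLS of per-condition mean value against site number.

    One regression point per site count in ``points_used`` (default: all
    available).  The parameter covariance comes from the residual variance;
    with only two points it is zero-filled and flagged via ``dof = 0``.
    """
    import statsmodels.api as sm

    if not ds.normalized:
        raise ParameterError("dataset must be normalized before fitting")
    means = ds.condition_means(genotype)
    if points_used is not None:
        missing = [p for p in points_used if p not in means.index]
        if missing:
            raise ParameterError(f"site counts {missing} not present for {genotype!r}")
        means = means.loc[list(points_used)]
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ParameterError("need at least 2 distinct site counts to fit a line")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    dof = len(x) - 2
    cov = np.asarray(res.cov_params()) if dof > 0 else np.zeros((2, 2))
    return LineFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        covariance=cov,
        n_points=len(x),
        points_used=tuple(int(v) for v in x),
        dof=dof,
    )


@dataclass(frozen=True)
class SlopeRatioEstimate:
    """Reference/mutant slope ratio with delta-method error."""

    ratio: float
    se: float
    ci95: tuple
    dof: float  # Satterthwaite effective degrees of freedom (inf for z interval)


def slope_ratio(
    fit_ref: LineFit, fit_mut: LineFit, ci_method: str = "t"
) -> SlopeRatioEstimate:
    """Ratio of fitted slopes, reference over mutant.

    First-order delta method with independent fits:
    ``var(r) = var(s_ref)/s_mut^2 + s_ref^2 var(s_mut)/s_mut^4``.
    The default 95% interval uses a Student-t quantile at the Satterthwaite
    effective degrees of freedom of the two variance components — with only
    a handful of regression points per genotype the normal quantile
    materially under-covers.  ``ci_method="z"`` gives the plain
    ``ratio ± 1.96 se`` interval.
    """
    s_ref, s_mut = fit_ref.slope, fit_mut.slope
    if s_mut == 0:
        raise ParameterError("mutant slope is zero; ratio undefined")
    r = s_ref / s_mut
    v_ref = fit_ref.covariance[1, 1] / s_mut**2
    v_mut = s_ref**2 * fit_mut.covariance[1, 1] / s_mut**4
    var = v_ref + v_mut
    se = math.sqrt(var)
    if ci_method == "z" or var == 0:
        q, dof = 1.959963984540054, math.inf
    elif ci_method == "t":
        denom = 0.0
        if fit_ref.dof > 0:
            denom += v_ref**2 / fit_ref.dof
        if fit_mut.dof > 0:
            denom += v_mut**2 / fit_mut.dof
        dof = var**2 / denom if denom > 0 else math.inf
        q = float(stats.t.ppf(0.975, dof)) if math.isfinite(dof) else 1.959963984540054
    else:
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    return SlopeRatioEstimate(ratio=r, se=se, ci95=(r - q * se, r + q * se), dof=dof)


@dataclass(frozen=True)
class NeEstimate:
    """Effective endogenous site number from the line-crossing abscissa."""

    n_e: float
    se: float


def estimate_ne(fit_ref: LineFit, fit_mut: LineFit) -> NeEstimate:
    """Minus the abscissa where the two fitted lines cross.

    With reference line ``b_r + s_r x`` and mutant line ``b_m + s_m x`` the
    crossing sits at ``x* = (b_m - b_r)/(s_r - s_m)`` and ``Ne = -x*``: both
    genotypes lose the same endogenous-site contribution, so extrapolating
    back to where their reporter levels coincide counts those sites.
    The standard error propagates the two (independent) fit covariances.
    """
    d = fit_ref.slope - fit_mut.slope
    if d == 0:
        raise ParameterError("fitted lines are parallel; no crossing")
    num = fit_mut.intercept - fit_ref.intercept
    n_e = -num / d
    # gradient of n_e wrt (b_ref, s_ref, b_mut, s_mut)
    g_ref = np.array([1.0 / d, num / d**2])
    g_mut = np.array([-1.0 / d, -num / d**2])
    var = g_ref @ fit_ref.covariance @ g_ref + g_mut @ fit_mut.covariance @ g_mut
    return NeEstimate(n_e=float(n_e), se=float(math.sqrt(max(var, 0.0))))


def infer_kp(
    fit_ref: LineFit, NICD0: float, Gamma_up: float, Gamma_p: float, n_e: float
) -> float:
    """Phosphorylation rate implied by the fitted normalized slope.

    Thin wrapper over the closed-form inversion in
    :func:`binddiscard.core.estimate_kp_from_slope`.
    """
    return core.estimate_kp_from_slope(fit_ref.slope, NICD0, Gamma_up, Gamma_p, n_e)


def analyze_reporter(
    ds: ReporterDataset,
    points_used_reference=None,
    points_used_mutant=None,
    NICD0: float | None = None,
    Gamma_up: float | None = None,
    Gamma_p: float | None = None,
) -> dict:
    """Full pipeline: normalize, fit both genotypes, ratio, Ne, optional kp.

    Returns a JSON-serialisable dict echoing the inputs used.
    """
    nds = normalize(ds)
    fit_ref = fit_line(nds, REFERENCE, points_used_reference)
    fit_mut = fit_line(nds, MUTANT, points_used_mutant)
    ratio = slope_ratio(fit_ref, fit_mut)
    ne = estimate_ne(fit_ref, fit_mut)
    out = {
        "normalization_constant": nds.normalization_constant,
        "fits": {
            name: {
                "slope": f.slope,
                "intercept": f.intercept,
                "slope_se": float(math.sqrt(f.covariance[1, 1])),
                "n_points": f.n_points,
                "points_used": list(f.points_used),
            }
            for name, f in ((REFERENCE, fit_ref), (MUTANT, fit_mut))
        },
        "ratio": {"value": ratio.ratio, "se": ratio.se, "ci95": list(ratio.ci95)},
        "ne": {"value": ne.n_e, "se": ne.se},
    }
    if NICD0 is not None and Gamma_up is not None and Gamma_p is not None:
        inputs = {"NICD0": NICD0, "Gamma_up": Gamma_up, "Gamma_p": Gamma_p, "N_e": ne.n_e}
        try:
            out["kp"] = {
                "value": infer_kp(fit_ref, NICD0, Gamma_up, Gamma_p, ne.n_e),
                "inputs": inputs,
            }
        except ParameterError as exc:
            # e.g. a noisy dataset whose estimated Ne came out negative
            out["kp"] = {"value": None, "inputs": inputs, "error": str(exc)}
    return out
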