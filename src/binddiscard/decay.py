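"""Hill-decay fitting of normalized luminescence curves.

Protein turnover read out by a split-luciferase signal often departs from a
single exponential (delayed onset, residual background), so half-lives are
extracted by fitting the decreasing Hill form

    f(t) = (t05^n + bg * t^n) / (t05^n + t^n)

with half-life ``t05``, Hill coefficient ``n`` and background fraction
``bg``.  ``f(0) = 1``, ``f(t05) = (1 + bg)/2`` identically, and ``f -> bg``
as ``t -> inf``.  Replicate wells are fitted jointly (pooled least squares);
95% intervals come from a seeded bootstrap by default, or from the
Gauss-Newton covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import ParameterError

__all__ = ["DecayCurve", "HillDecayFit", "hill_decay", "fit_hill_decay"]


def hill_decay(t, t05: float, n_hill: float, bg: float):
    """Decreasing Hill curve; scalar or array ``t`` in minutes."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    if not t05 > 0:
        raise ParameterError(f"t05 must be positive, got {t05!r}")
    if not n_hill > 0:
        raise ParameterError(f"n_hill must be positive, got {n_hill!r}")
    if not 0 <= bg < 1:
        raise ParameterError(f"bg must be in [0, 1), got {bg!r}")
    tn = (t / t05) ** n_hill  # scale first: avoids overflow for large t, n
    out = (1.0 + bg * tn) / (1.0 + tn)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DecayCurve:
    """Normalized decay series, one or more replicates on a shared time grid.

    ``data`` columns: ``time_min``, ``replicate``, ``value``; each replicate
    must start at t=0 with value 1 (the assay normalizes each well to its
    own first reading) and have at least 4 timepoints.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"time_min", "replicate", "value"}
        if not need <= set(self.data.columns):
            raise ParameterError(f"decay table needs columns {sorted(need)}")
        for rep, sub in self.data.groupby("replicate"):
            sub = sub.sort_values("time_min")
            if len(sub) < 4:
                raise ParameterError(f"replicate {rep!r} has fewer than 4 timepoints")
            t = sub["time_min"].to_numpy()
            if t[0] != 0 or np.any(np.diff(t) <= 0):
                raise ParameterError(
                    f"replicate {rep!r} times must start at 0 and increase"
                )
            if abs(sub["value"].iloc[0] - 1.0) > 1e-6:
                raise ParameterError(
                    f"replicate {rep!r} is not normalized to 1 at t=0"
                )

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    @classmethod
    def from_csv(cls, path) -> "DecayCurve":
        return cls(data=pd.read_csv(path)[["time_min", "replicate", "value"]])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class HillDecayFit:
    """Fitted Hill-decay parameters with per-parameter 95% intervals."""

    t05: float
    n_hill: float
    bg: float
    rss: float
    ci95: dict  # parameter name -> (low, high)
    ci_method: str
    seed: int | None


_N_MAX = 10.0


def _fit_pooled(t: np.ndarray, v: np.ndarray, p0=None) -> np.ndarray:
    if p0 is None:
        bg0 = float(max(min(v.min(), 0.98), 0.0))
        target = (1.0 + bg0) / 2.0
        t05_0 = float(t[np.argmin(np.abs(v - target))])
        if t05_0 <= 0:
            t05_0 = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
        p0 = [t05_0, 2.0, bg0]
    popt, _ = curve_fit(
        lambda tt, t05, n, bg: (1.0 + bg * (tt / t05) ** n) / (1.0 + (tt / t05) ** n),
        t,
        v,
        p0=p0,
        bounds=([1e-9, 1e-6, 0.0], [np.inf, _N_MAX, 1.0 - 1e-9]),
        maxfev=20000,
    )
    return popt


def fit_hill_decay(
    curve: DecayCurve,
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> HillDecayFit:
    """Pooled nonlinear least squares of the Hill decay over all replicates.

    Initialization: ``bg0 = min(value)``, ``t05_0`` the time whose value is
    closest to ``(1 + bg0)/2``, ``n0 = 2``.  Confidence intervals: with
    ``ci_method="bootstrap"`` (default), replicate curves are resampled with
    replacement (residual resampling when there is a single replicate),
    each resample refitted, and the 2.5/97.5 percentiles reported; with
    ``"covariance"``, the linearised covariance from the least-squares fit
    is used.  Deterministic given ``seed``.
    """
    df = curve.data.sort_values(["replicate", "time_min"])
    t = df["time_min"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if np.allclose(v, v[0]):
        raise ParameterError("decay values are constant; nothing to fit")

    try:
        popt = _fit_pooled(t, v)
    except RuntimeError as exc:
        raise RuntimeError(f"Hill-decay fit did not converge: {exc}") from exc
    t05, n_hill, bg = (float(x) for x in popt)
    resid = v - hill_decay(t, t05, n_hill, bg)
    rss = float(resid @ resid)

    names = ("t05", "n_hill", "bg")
    if ci_method == "covariance":
        _, pcov = curve_fit(
            lambda tt, a, b, c: hill_decay(tt, a, b, c),
            t,
            v,
            p0=popt,
            bounds=([1e-9, 1e-6, 0.0], [np.inf, _N_MAX, 1.0 - 1e-9]),
            maxfev=20000,
        )
        se = np.sqrt(np.diag(pcov))
        ci = {
            nm: (float(p - 1.96 * s), float(p + 1.96 * s))
            for nm, p, s in zip(names, popt, se)
        }
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = curve.replicates
        groups = {r: g for r, g in df.groupby("replicate")}
        samples = []
        for _ in range(n_boot):
            if len(reps) > 1:
                chosen = rng.choice(reps, size=len(reps), replace=True)
                tb = np.concatenate([groups[r]["time_min"].to_numpy() for r in chosen])
                vb = np.concatenate([groups[r]["value"].to_numpy() for r in chosen])
            else:
                vb = hill_decay(t, t05, n_hill, bg) + rng.choice(
                    resid, size=len(resid), replace=True
                )
                tb = t
            try:
                samples.append(_fit_pooled(tb, vb, p0=list(popt)))
            except RuntimeError:
                continue
        if len(samples) < max(10, n_boot // 10):
            raise RuntimeError("too few successful bootstrap refits")
        arr = np.array(samples)
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
        ci = {nm: (float(a), float(b)) for nm, a, b in zip(names, lo, hi)}
    else:
        raise ParameterError(f"unknown ci_method {ci_method!r}")

    return HillDecayFit(
        t05=t05,
        n_hill=n_hill,
        bg=bg,
        rss=rss,
        ci95=ci,
        ci_method=ci_method,
        seed=seed,
    )
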