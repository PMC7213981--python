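"""Deterministic model of binding-site-coupled NICD degradation.

The model reduces the full reaction network (production, site binding and
unbinding, Cdk8 phosphorylation of bound NICD, state-dependent degradation)
to two slow variables — total unphosphorylated NICD ``u`` and total
phosphorylated NICD ``p`` — by assuming site binding equilibrates much faster
than production/degradation.  Site occupancy then follows a single-site
partition function

    Z = 1 + u/k_alpha + p/k_alpha,

with per-site probabilities ``p_up = (u/k_alpha)/Z`` and ``p_p = (p/k_alpha)/Z``
of carrying unphosphorylated or phosphorylated NICD.  With ``N = N_e + N_s``
identical independent sites, the dimensionless-rate steady state solves

    0 = NICD0 - u - N p_up (k_p' - 1)
    0 = N p_up k_p' - (p - N p_p) Gamma_p'

where primes denote rates in units of Gamma_up.  The ``-1`` in ``k_p' - 1``
is the sequestration correction: a bound molecule is protected from the
basal degradation channel.  Physical-time dynamics multiply the right-hand
sides by Gamma_up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import KineticParams, ParameterError

__all__ = [
    "SiteOccupancy",
    "SteadyState",
    "Trajectory",
    "LinearRegimeResult",
    "KpGrid",
    "DurationSensitivity",
    "site_occupancy",
    "steady_state",
    "integrate_dynamics",
    "linear_regime",
    "estimate_kp_from_slope",
    "kp_grid",
    "titration_curve",
    "duration_sensitivity",
    "robustness_sweep",
]

#: linear-regime validity: (N_e+N_s) * k_p' * (1 - 1/Gamma_p') <= this * NICD0
LINEAR_VALIDITY_FACTOR = 0.3


class ConvergenceError(RuntimeError):
    """Steady-state solver failed to converge; carries the best residual."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


class IntegrationError(RuntimeError):
    """ODE integration failed."""


# ---------------------------------------------------------------------------
# Occupancy


@dataclass(frozen=True)
class SiteOccupancy:
    """Single-site equilibrium occupancy of an SPS by the NICD complex."""

    alpha_up: float  # statistical weight of the unphosphorylated-bound state
    alpha_p: float  # statistical weight of the phosphorylated-bound state
    Z: float  # partition function, 1 + alpha_up + alpha_p
    p_empty: float
    p_up: float
    p_p: float


def site_occupancy(nicd_up: float, nicd_p: float, k_alpha: float) -> SiteOccupancy:
    """Equilibrium occupancy of one SPS given the free-energy weights.

    ``alpha_up = NICD_up / k_alpha`` and ``alpha_p = NICD_p / k_alpha`` are the
    statistical weights of the two bound states against the empty state
    (weight 1); probabilities are weights normalised by the partition
    function.
    """
    for name, v in (("nicd_up", nicd_up), ("nicd_p", nicd_p)):
        if not (math.isfinite(v) and v >= 0):
            raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
    if not (math.isfinite(k_alpha) and k_alpha > 0):
        raise ParameterError(f"k_alpha must be positive, got {k_alpha!r}")
    a_up = nicd_up / k_alpha
    a_p = nicd_p / k_alpha
    Z = 1.0 + a_up + a_p
    return SiteOccupancy(
        alpha_up=a_up,
        alpha_p=a_p,
        Z=Z,
        p_empty=1.0 / Z,
        p_up=a_up / Z,
        p_p=a_p / Z,
    )


# ---------------------------------------------------------------------------
# Steady state


@dataclass(frozen=True)
class SteadyState:
    """Solved steady state of the nuclear NICD pools."""

    NICD_up: float
    NICD_p: float
    NICD_tot: float
    NICD_up_b: float
    NICD_p_b: float
    NICD_up_ub: float
    NICD_p_ub: float
    occupancy: SiteOccupancy
    residual_norm: float
    converged: bool


def _residuals(u: float, p: float, params: KineticParams) -> tuple[float, float]:
    N = params.n_sites_total
    D = params.k_alpha + u + p
    pup = u / D
    pp = p / D
    f1 = params.NICD0 - u - N * pup * (params.k_p_prime - 1.0)
    f2 = N * pup * params.k_p_prime - params.Gamma_p_prime * (p - N * pp)
    return f1, f2


def _jacobian(u: float, p: float, params: KineticParams) -> np.ndarray:
    N = params.n_sites_total
    kpp = params.k_p_prime
    gpp = params.Gamma_p_prime
    D = params.k_alpha + u + p
    D2 = D * D
    ka = params.k_alpha
    return np.array(
        [
            [-1.0 - N * (kpp - 1.0) * (ka + p) / D2, N * (kpp - 1.0) * u / D2],
            [
                N * kpp * (ka + p) / D2 + gpp * N * p / D2,
                -N * kpp * u / D2 - gpp + gpp * N * (ka + u) / D2,
            ],
        ]
    )


def steady_state(params: KineticParams, tol_factor: float = 1e-10) -> SteadyState:
    """Nonnegative root of the two coupled steady-state equations.

    Multistart root finding (analytic Jacobian) from three initial guesses;
    a root is accepted when the max residual is below ``tol_factor * NICD0``
    and both pools are nonnegative (values above -1e-9 are clipped to zero).
    """
    if params.NICD0 <= 0:
        raise ParameterError("steady_state requires NICD0 > 0")
    N = params.n_sites_total
    if N == 0:
        # no sites: u relaxes to NICD0, nothing is ever phosphorylated
        occ = site_occupancy(params.NICD0, 0.0, params.k_alpha)
        return SteadyState(
            NICD_up=params.NICD0,
            NICD_p=0.0,
            NICD_tot=params.NICD0,
            NICD_up_b=0.0,
            NICD_p_b=0.0,
            NICD_up_ub=params.NICD0,
            NICD_p_ub=0.0,
            occupancy=occ,
            residual_norm=0.0,
            converged=True,
        )

    tol = tol_factor * params.NICD0
    starts = [
        (params.NICD0, 1e-8 * params.NICD0),
        (params.NICD0 / 2.0, params.NICD0 / 10.0),
        (1e-8 * params.NICD0, 1e-8 * params.NICD0),
    ]
    best = math.inf
    for u0, p0 in starts:
        sol = root(
            lambda y: _residuals(y[0], y[1], params),
            x0=[u0, p0],
            jac=lambda y: _jacobian(y[0], y[1], params),
            method="hybr",
            tol=1e-14,
        )
        u, p = sol.x
        if u < -1e-9 or p < -1e-9:
            continue
        u = max(u, 0.0)
        p = max(p, 0.0)
        res = max(abs(r) for r in _residuals(u, p, params))
        best = min(best, res)
        if res <= tol:
            occ = site_occupancy(u, p, params.k_alpha)
            return SteadyState(
                NICD_up=u,
                NICD_p=p,
                NICD_tot=u + p,
                NICD_up_b=N * occ.p_up,
                NICD_p_b=N * occ.p_p,
                NICD_up_ub=u - N * occ.p_up,
                NICD_p_ub=p - N * occ.p_p,
                occupancy=occ,
                residual_norm=res,
                converged=True,
            )
    raise ConvergenceError(
        f"steady-state solver did not converge (best residual {best:.3e}, "
        f"tolerance {tol:.3e})",
        best_residual=best,
    )


# ---------------------------------------------------------------------------
# Dynamics


@dataclass(frozen=True)
class Trajectory:
    """Time course of the NICD pools."""

    times: np.ndarray  # min (or units of 1/Gamma_up in dimensionless mode)
    NICD_up_t: np.ndarray
    NICD_p_t: np.ndarray

    @property
    def NICD_tot_t(self) -> np.ndarray:
        return self.NICD_up_t + self.NICD_p_t


def _rhs(t, y, params: KineticParams, scale: float):
    f1, f2 = _residuals(y[0], y[1], params)
    return [scale * f1, scale * f2]


def integrate_dynamics(
    params: KineticParams,
    t_grid,
    initial: tuple[float, float] = (0.0, 0.0),
    dimensionless_time: bool = False,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the reduced two-variable dynamics on ``t_grid``.

    Time is physical (minutes) by default; the printed dimensionless system
    (time in units of 1/Gamma_up) is available with ``dimensionless_time``.
    Uses a stiff-capable solver (LSODA) with ``atol = 1e-10 * NICD0``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ParameterError("t_grid must be a 1-D array of at least two times")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ParameterError("t_grid must start at 0 and be strictly increasing")
    u0, p0 = initial
    if u0 < 0 or p0 < 0:
        raise ParameterError("initial pools must be nonnegative")

    scale = 1.0 if dimensionless_time else params.Gamma_up
    sol = solve_ivp(
        _rhs,
        (t_grid[0], t_grid[-1]),
        [u0, p0],
        t_eval=t_grid,
        args=(params, scale),
        method="LSODA",
        rtol=rtol,
        atol=1e-10 * max(params.NICD0, 1.0),
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    u = np.clip(sol.y[0], 0.0, None)
    p = np.clip(sol.y[1], 0.0, None)
    return Trajectory(times=t_grid, NICD_up_t=u, NICD_p_t=p)


# ---------------------------------------------------------------------------
# Linear regime and kp estimation


@dataclass(frozen=True)
class LinearRegimeResult:
    """Closed-form linear-regime slope and intercept of NICD_tot vs N_s."""

    slope_dimensionless: float  # per added site, in molecules/nucleus
    intercept: float  # NICD_tot at N_s = 0, molecules/nucleus
    slope_normalized: float  # per-site slope of NICD_tot / NICD_tot(N_s=0)
    valid: bool  # inside the configured linear-validity envelope
    approximation_ok: bool  # False when Gamma_p' <= 1 (fast-decay premise broken)


def linear_regime(
    params: KineticParams, validity_factor: float = LINEAR_VALIDITY_FACTOR
) -> LinearRegimeResult:
    """Linear-regime slope of steady-state NICD_tot against site number.

    Valid for few sites and ``k_p >> Gamma_up``: each added site removes
    ``k_p' (1 - 1/Gamma_p')`` molecules, so

        slope = -k_p' (1 - 1/Gamma_p'),
        intercept = NICD0 - N_e k_p' (1 - 1/Gamma_p').

    The normalized slope divides by the intercept (the N_s = 0 level).
    """
    c = 1.0 - 1.0 / params.Gamma_p_prime
    slope = -params.k_p_prime * c
    intercept = params.NICD0 + params.N_e * slope
    load = params.n_sites_total * params.k_p_prime * c
    return LinearRegimeResult(
        slope_dimensionless=slope,
        intercept=intercept,
        slope_normalized=slope / intercept,
        valid=load <= validity_factor * params.NICD0,
        approximation_ok=params.Gamma_p_prime > 1.0,
    )


def estimate_kp_from_slope(
    slope_normalized: float,
    NICD0: float,
    Gamma_up: float,
    Gamma_p: float,
    N_e: float,
) -> float:
    """Invert the normalized linear-regime slope for the phosphorylation rate.

    Closed form: with ``s`` the per-site slope of the normalized titration
    curve and ``c = 1 - Gamma_up/Gamma_p``,

        k_p = NICD0 * Gamma_up / ((N_e - 1/s) * c),

    the exact inverse of the normalized-slope expression (``s = 0`` maps to
    ``k_p = 0`` as the limiting case).
    """
    if not math.isfinite(slope_normalized) or slope_normalized > 0:
        raise ParameterError(
            f"slope_normalized must be finite and <= 0, got {slope_normalized!r}"
        )
    for name, v in (("NICD0", NICD0), ("Gamma_up", Gamma_up), ("Gamma_p", Gamma_p)):
        if not (math.isfinite(v) and v > 0):
            raise ParameterError(f"{name} must be positive, got {v!r}")
    if N_e < 0:
        raise ParameterError(f"N_e must be >= 0, got {N_e!r}")
    if slope_normalized == 0.0:
        return 0.0
    c = 1.0 - Gamma_up / Gamma_p
    denom = (N_e - 1.0 / slope_normalized) * c
    if denom <= 0:
        raise ParameterError(
            f"slope {slope_normalized} implies non-positive k_p (denominator {denom})"
        )
    kp = NICD0 * Gamma_up / denom
    if not math.isfinite(kp) or kp <= 0:
        raise ParameterError(
            f"slope {slope_normalized} implies non-positive k_p (denominator {denom})"
        )
    return kp


@dataclass(frozen=True)
class KpGrid:
    """Grid of phosphorylation rates implied by a measured normalized slope."""

    NICD0_values: np.ndarray
    Gamma_up_values: np.ndarray
    kp_values: np.ndarray  # shape (len(Gamma_up_values), len(NICD0_values)); NaN = masked
    slope_normalized: float
    N_e: float
    Gamma_p: float


def kp_grid(
    NICD0_range,
    Gamma_up_range,
    Gamma_p: float,
    slope_normalized: float,
    N_e: float,
) -> KpGrid:
    """Element-wise phosphorylation-rate estimates over an abundance/decay grid.

    Cells whose inversion is out of domain are masked as NaN.
    """
    n0 = np.asarray(NICD0_range, dtype=float)
    gu = np.asarray(Gamma_up_range, dtype=float)
    kp = np.full((len(gu), len(n0)), np.nan)
    for i, g in enumerate(gu):
        for j, n in enumerate(n0):
            try:
                kp[i, j] = estimate_kp_from_slope(slope_normalized, n, g, Gamma_p, N_e)
            except ParameterError:
                pass
    return KpGrid(
        NICD0_values=n0,
        Gamma_up_values=gu,
        kp_values=kp,
        slope_normalized=slope_normalized,
        N_e=N_e,
        Gamma_p=Gamma_p,
    )


# ---------------------------------------------------------------------------
# Titration curves


def titration_curve(params: KineticParams, Ns_values):
    """Steady-state NICD_tot at each synthetic-site count.

    Returns a pandas DataFrame with columns ``n_sites``, ``nicd_up``,
    ``nicd_p``, ``nicd_tot`` and ``nicd_tot_norm`` (normalized to the
    ``N_s = 0`` value, which must be included).
    """
    import pandas as pd

    ns = list(Ns_values)
    if 0 not in ns:
        raise ParameterError("Ns_values must include 0 (the normalization point)")
    rows = []
    for n in ns:
        ss = steady_state(params.replace(N_s=int(n)))
        rows.append((int(n), ss.NICD_up, ss.NICD_p, ss.NICD_tot))
    df = pd.DataFrame(rows, columns=["n_sites", "nicd_up", "nicd_p", "nicd_tot"])
    base = df.loc[df.n_sites == 0, "nicd_tot"].iloc[0]
    df["nicd_tot_norm"] = df["nicd_tot"] / base
    return df


# ---------------------------------------------------------------------------
# Duration sensitivity


@dataclass(frozen=True)
class DurationSensitivity:
    """Fractional NICD reductions from added sites vs halved production.

    Reductions are relative to the wild-type trajectory at the same time,
    all trajectories starting from empty nuclei at signal onset.
    """

    t_short: float
    t_long: float
    reduction_by_sites_short: float
    reduction_by_sites_long: float
    reduction_by_halved_production_short: float
    reduction_by_halved_production_long: float
    near_steady_state: bool  # long-time wt level within 1% of the solved steady state


def duration_sensitivity(
    params_wt: KineticParams,
    Ns_transgene: int,
    t_short: float,
    t_long: float,
) -> DurationSensitivity:
    """Compare transient NICD loss from extra sites against halved production.

    Integrates three trajectories from ``(0, 0)``: wild type, wild type plus
    ``Ns_transgene`` synthetic sites, and a production heterozygote with
    ``P_NICD`` halved.  This is the model's account of why tissues needing
    only a short pulse of Notch signal tolerate extra degradation sites but
    not a lost receptor allele.
    """
    if not 0 < t_short < t_long:
        raise ParameterError("need 0 < t_short < t_long")
    t_grid = np.array([0.0, t_short, t_long])
    wt = integrate_dynamics(params_wt, t_grid)
    sites = integrate_dynamics(params_wt.replace(N_s=int(Ns_transgene)), t_grid)
    het = integrate_dynamics(params_wt.replace(NICD0=params_wt.NICD0 / 2.0), t_grid)

    wt_tot = wt.NICD_tot_t
    with np.errstate(invalid="ignore", divide="ignore"):  # t=0 is 0/0, unused
        red_sites = 1.0 - sites.NICD_tot_t / wt_tot
        red_het = 1.0 - het.NICD_tot_t / wt_tot
    ss = steady_state(params_wt)
    near = abs(wt_tot[2] - ss.NICD_tot) <= 0.01 * ss.NICD_tot
    return DurationSensitivity(
        t_short=t_short,
        t_long=t_long,
        reduction_by_sites_short=float(red_sites[1]),
        reduction_by_sites_long=float(red_sites[2]),
        reduction_by_halved_production_short=float(red_het[1]),
        reduction_by_halved_production_long=float(red_het[2]),
        near_steady_state=bool(near),
    )


def robustness_sweep(
    base: KineticParams,
    variants,
    Ns_transgene: int = 12,
    t_short: float = 10.0,
    t_long: float = 1e5,
    slope_normalized: float | None = None,
):
    """Duration-sensitivity outcomes across parameter variants.

    ``variants`` is a list of ``(label, overrides)`` pairs or plain override
    dicts.  When ``slope_normalized`` is given, each variant's ``k_p`` is
    re-estimated from that measured slope under the variant's own
    ``NICD0``/``Gamma_up``/``Gamma_p`` (the calibration used for the duration
    analyses).  Per-variant errors are recorded and the sweep continues.
    Returns a DataFrame with one row per variant, flagging variants where the
    short-time site effect is NOT below half the halved-production effect.
    """
    import pandas as pd

    rows = []
    for k, item in enumerate(variants):
        if isinstance(item, tuple):
            label, overrides = item
        else:
            label, overrides = f"variant_{k}", item
        try:
            p = base.replace(**overrides)
            if slope_normalized is not None:
                kp = estimate_kp_from_slope(
                    slope_normalized, p.NICD0, p.Gamma_up, p.Gamma_p, p.N_e
                )
                p = p.replace(k_p=kp)
            d = duration_sensitivity(p, Ns_transgene, t_short, t_long)
            rows.append(
                dict(
                    label=label,
                    k_p=p.k_p,
                    reduction_by_sites_short=d.reduction_by_sites_short,
                    reduction_by_halved_production_short=d.reduction_by_halved_production_short,
                    reduction_by_sites_long=d.reduction_by_sites_long,
                    reduction_by_halved_production_long=d.reduction_by_halved_production_long,
                    short_ordering_ok=d.reduction_by_sites_short
                    < 0.5 * d.reduction_by_halved_production_short,
                    error="",
                )
            )
        except Exception as exc:  # record and continue
            rows.append(
                dict(
                    label=label,
                    k_p=np.nan,
                    reduction_by_sites_short=np.nan,
                    reduction_by_halved_production_short=np.nan,
                    reduction_by_sites_long=np.nan,
                    reduction_by_halved_production_long=np.nan,
                    short_ordering_ok=False,
                    error=str(exc),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "k_p",
            "reduction_by_sites_short",
            "reduction_by_halved_production_short",
            "reduction_by_sites_long",
            "reduction_by_halved_production_long",
            "short_ordering_ok",
            "error",
        ],
    )
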