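"""Exact event-driven stochastic simulation of the full NICD reaction network.

Serves as an independent oracle for the deterministic reduced model: the
network is simulated with discrete molecules and discrete binding sites, with
no timescale-separation or large-copy-number assumptions.  Reactions (rates
are mass-action propensities):

    0 -> up_ub                      P_NICD
    up_ub -> 0                      Gamma_up * n_up_ub
    p_ub  -> 0                      Gamma_p  * n_p_ub
    up_ub + site -> bound_up        k_on * n_up_ub * n_free
    bound_up -> up_ub + site        k_off * n_bound_up
    p_ub + site -> bound_p          k_on * n_p_ub * n_free
    bound_p -> p_ub + site          k_off * n_bound_p
    bound_up -> bound_p             k_p * n_bound_up

Sites are identical and independent; bound molecules are protected from
degradation.  The direct (Gillespie) method is used, with state recorded on
a fixed grid (the value at a grid time is the state just before the first
jump past it).  The inner loop is compiled with numba when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import KineticParams, ParameterError

__all__ = ["SSAResult", "simulate_ssa"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _ssa_kernel(P, gup, gp, kon, koff, kp, n_sites, t_end, record, seed):  # pragma: no cover
    np.random.seed(seed)
    n_rec = record.shape[0]
    out = np.zeros((n_rec, 4), dtype=np.int64)
    u_ub = 0
    p_ub = 0
    b_up = 0
    b_p = 0
    t = 0.0
    i_rec = 0
    n_events = 0
    props = np.zeros(8)
    while t < t_end:
        free = n_sites - b_up - b_p
        props[0] = P
        props[1] = gup * u_ub
        props[2] = gp * p_ub
        props[3] = kon * u_ub * free
        props[4] = koff * b_up
        props[5] = kon * p_ub * free
        props[6] = koff * b_p
        props[7] = kp * b_up
        total = (
            props[0] + props[1] + props[2] + props[3]
            + props[4] + props[5] + props[6] + props[7]
        )
        if total <= 0.0:
            t = t_end
        else:
            t += -math.log(np.random.random()) / total
        while i_rec < n_rec and record[i_rec] <= t:
            out[i_rec, 0] = u_ub
            out[i_rec, 1] = p_ub
            out[i_rec, 2] = b_up
            out[i_rec, 3] = b_p
            i_rec += 1
        if t >= t_end:
            break
        r = np.random.random() * total
        acc = 0.0
        idx = 0
        for k in range(8):
            acc += props[k]
            if r < acc:
                idx = k
                break
        if idx == 0:
            u_ub += 1
        elif idx == 1:
            u_ub -= 1
        elif idx == 2:
            p_ub -= 1
        elif idx == 3:
            u_ub -= 1
            b_up += 1
        elif idx == 4:
            u_ub += 1
            b_up -= 1
        elif idx == 5:
            p_ub -= 1
            b_p += 1
        elif idx == 6:
            p_ub += 1
            b_p -= 1
        else:
            b_up -= 1
            b_p += 1
        n_events += 1
        # site conservation is structural; guard against coding errors
        if b_up + b_p > n_sites or u_ub < 0 or p_ub < 0 or b_up < 0 or b_p < 0:
            return out, -1
    return out, n_events


@dataclass(frozen=True)
class SSAResult:
    """Recorded stochastic trajectory and post-burn-in summary."""

    times: np.ndarray
    n_up_ub: np.ndarray
    n_p_ub: np.ndarray
    n_bound_up: np.ndarray
    n_bound_p: np.ndarray
    mean_tot: float  # time-averaged NICD_tot over the averaging window
    se_tot: float  # batch-means standard error of the mean
    n_events: int
    seed: int
    burn_in: float

    @property
    def nicd_tot(self) -> np.ndarray:
        return self.n_up_ub + self.n_p_ub + self.n_bound_up + self.n_bound_p

    def to_frame(self):
        import pandas as pd

        tot = self.nicd_tot
        return pd.DataFrame(
            {
                "t_min": self.times,
                "nicd_up": self.n_up_ub + self.n_bound_up,
                "nicd_p": self.n_p_ub + self.n_bound_p,
                "nicd_tot": tot,
                "nicd_tot_norm": tot / tot[-1] if tot[-1] else np.nan,
            }
        )

    def summary(self) -> dict:
        return {
            "mean": self.mean_tot,
            "se": self.se_tot,
            "n_events": self.n_events,
            "seed": self.seed,
        }


def simulate_ssa(
    params: KineticParams,
    t_end: float,
    seed: int,
    record_dt: float = 1.0,
    burn_in: float | None = None,
    n_batches: int = 20,
) -> SSAResult:
    """Run the direct-method simulation and summarise the stationary window.

    ``burn_in`` defaults to ``10 / Gamma_up`` (ten basal lifetimes, the
    slowest relaxation scale); the remainder of the run is the averaging
    window, whose mean and batch-means standard error of ``NICD_tot`` are
    reported.  ``round(N_e + N_s)`` discrete sites are simulated.
    Reproducible given ``seed``.
    """
    if params.k_on is None or params.k_off is None:
        raise ParameterError("simulate_ssa requires explicit k_on and k_off")
    if seed is None:
        raise ParameterError("seed is required")
    if burn_in is None:
        burn_in = 10.0 / params.Gamma_up
    if t_end <= burn_in:
        raise ParameterError(
            f"t_end={t_end} must exceed the burn-in window {burn_in}"
        )
    n_sites = int(round(params.n_sites_total))
    record = np.arange(0.0, t_end, record_dt)
    out, n_events = _ssa_kernel(
        params.P_NICD,
        params.Gamma_up,
        params.Gamma_p,
        params.k_on,
        params.k_off,
        params.k_p,
        n_sites,
        float(t_end),
        record,
        int(seed) % (2**32),
    )
    if n_events < 0:
        raise RuntimeError("state invariant violated in SSA kernel")
    tot = out.sum(axis=1).astype(float)
    window = record >= burn_in
    w = tot[window]
    nb = min(n_batches, max(2, len(w) // 2))
    batches = np.array_split(w, nb)
    bm = np.array([b.mean() for b in batches])
    mean = w.mean()
    se = bm.std(ddof=1) / math.sqrt(nb)
    return SSAResult(
        times=record,
        n_up_ub=out[:, 0],
        n_p_ub=out[:, 1],
        n_bound_up=out[:, 2],
        n_bound_p=out[:, 3],
        mean_tot=float(mean),
        se_tot=float(se),
        n_events=int(n_events),
        seed=int(seed),
        burn_in=float(burn_in),
    )
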