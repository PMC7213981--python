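"""Kinetic parameters of the nuclear NICD turnover model.

Units are molecules per nucleus and minutes throughout; no volumes or molar
concentrations.  The model tracks the Notch intracellular domain (NICD) in a
single nucleus: NICD enters at a constant production rate ``P_NICD``, binds
Su(H)-paired sites (SPS) as part of the NICD/CSL/Mastermind complex, is
phosphorylated by the Cdk8 kinase module while bound (rate ``k_p``), and is
degraded at rate ``Gamma_up`` when unphosphorylated and ``Gamma_p`` (faster)
when phosphorylated.

Convention: degradation rates and half-lives are paired as ``half_life = 1/Gamma``
(not ``ln2/Gamma``).  A rate of 1/120 min^-1 therefore corresponds to a
"120-minute half-life" wherever the documentation says so.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = ["KineticParams", "load_preset", "available_presets"]


class ParameterError(ValueError):
    """Invalid or inconsistent kinetic parameters."""


@dataclass(frozen=True)
class KineticParams:
    """Rate and abundance parameters of the NICD model.

    Parameters
    ----------
    Gamma_up : float
        Degradation rate of unbound, unphosphorylated NICD (min^-1).
    Gamma_p : float
        Degradation rate of unbound, phosphorylated NICD (min^-1).
    k_p : float
        Phosphorylation rate of bound, unphosphorylated NICD (min^-1).
    NICD0 : float, optional
        Baseline steady-state abundance ``P_NICD / Gamma_up`` (molecules per
        nucleus).  Exactly one of ``NICD0`` / ``P_NICD`` may be omitted.
    P_NICD : float, optional
        Nuclear entry (production) rate (molecules min^-1).
    k_alpha : float
        Dissociation constant of the NICD-complex/SPS interaction (molecules
        per nucleus).  The default of 1 puts the model deep in the
        strong-binding regime, where steady-state results are insensitive to
        its value.
    N_e : float
        Effective number of endogenous SPS-equivalent sites (real-valued).
    N_s : int
        Number of synthetic SPS sites.
    k_on, k_off : float, optional
        Explicit association (molecules^-1 min^-1) and dissociation (min^-1)
        rates.  Only the stochastic simulator needs them; when both are given
        they must satisfy ``k_off / k_on == k_alpha``.
    """

    Gamma_up: float
    Gamma_p: float
    k_p: float
    NICD0: float | None = None
    P_NICD: float | None = None
    k_alpha: float = 1.0
    N_e: float = 0.0
    N_s: int = 0
    k_on: float | None = None
    k_off: float | None = None

    def __post_init__(self) -> None:
        for name in ("Gamma_up", "Gamma_p", "k_alpha"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be a finite positive rate, got {v!r}")
        if not (math.isfinite(self.k_p) and self.k_p >= 0):
            raise ParameterError(f"k_p must be finite and >= 0, got {self.k_p!r}")
        if not (math.isfinite(self.N_e) and self.N_e >= 0):
            raise ParameterError(f"N_e must be >= 0, got {self.N_e!r}")
        if not (float(self.N_s).is_integer() and self.N_s >= 0):
            raise ParameterError(f"N_s must be a nonnegative integer, got {self.N_s!r}")

        if self.NICD0 is None and self.P_NICD is None:
            raise ParameterError("one of NICD0 or P_NICD is required")
        if self.NICD0 is None:
            object.__setattr__(self, "NICD0", self.P_NICD / self.Gamma_up)
        elif self.P_NICD is None:
            object.__setattr__(self, "P_NICD", self.NICD0 * self.Gamma_up)
        else:
            expected = self.P_NICD / self.Gamma_up
            if abs(self.NICD0 - expected) > 1e-12 * max(abs(expected), 1.0):
                raise ParameterError(
                    f"NICD0={self.NICD0} inconsistent with P_NICD/Gamma_up={expected}"
                )
        if self.NICD0 < 0:
            raise ParameterError("NICD0 must be nonnegative")

        if (self.k_on is None) != (self.k_off is None):
            raise ParameterError("k_on and k_off must be given together")
        if self.k_on is not None:
            if self.k_on <= 0 or self.k_off <= 0:
                raise ParameterError("k_on and k_off must be positive")
            ka = self.k_off / self.k_on
            if abs(ka - self.k_alpha) > 1e-9 * self.k_alpha:
                raise ParameterError(
                    f"k_off/k_on={ka} inconsistent with k_alpha={self.k_alpha}"
                )

    # -- derived dimensionless parameters ------------------------------------
    @property
    def Gamma_p_prime(self) -> float:
        """Gamma_p / Gamma_up (dimensionless)."""
        return self.Gamma_p / self.Gamma_up

    @property
    def k_p_prime(self) -> float:
        """k_p / Gamma_up (dimensionless)."""
        return self.k_p / self.Gamma_up

    @property
    def n_sites_total(self) -> float:
        """Total SPS-equivalent site count N = N_e + N_s."""
        return self.N_e + self.N_s

    def replace(self, **changes) -> "KineticParams":
        """Return a copy with fields replaced.

        Changing any of ``NICD0``, ``P_NICD`` or ``Gamma_up`` alone re-derives
        the production/abundance pairing instead of raising an inconsistency
        error: set ``NICD0`` and the production rate follows, and vice versa.
        """
        if "NICD0" in changes and "P_NICD" not in changes:
            changes["P_NICD"] = None
        elif "P_NICD" in changes and "NICD0" not in changes:
            changes["NICD0"] = None
        elif "Gamma_up" in changes and not {"NICD0", "P_NICD"} & changes.keys():
            # keep the abundance, re-derive production
            changes["P_NICD"] = None
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Presets

_PRESET_PKG = "binddiscard.presets"


def available_presets() -> list[str]:
    """Names of the packaged parameter presets."""
    names = []
    for entry in resources.files(_PRESET_PKG).iterdir():
        if entry.name.endswith(".yaml"):
            names.append(entry.name[: -len(".yaml")])
    return sorted(names)


def load_preset(name: str) -> dict:
    """Load a packaged preset as a plain dict.

    Presets are YAML mappings; the ``params`` block (when present) can be fed
    to :class:`KineticParams` directly.  Values given as strings of the form
    ``"1/120"`` are evaluated as rational rates.
    """
    ref = resources.files(_PRESET_PKG).joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")
    return _eval_fractions(yaml.safe_load(text))


def preset_params(name: str) -> KineticParams:
    """Load a preset's ``params`` block as :class:`KineticParams`."""
    data = load_preset(name)
    return KineticParams(**data["params"])


def _eval_fractions(obj):
    if isinstance(obj, dict):
        return {k: _eval_fractions(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_eval_fractions(v) for v in obj]
    if isinstance(obj, str) and "/" in obj:
        num, _, den = obj.partition("/")
        try:
            return float(num) / float(den)
        except ValueError:
            return obj
    return obj
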