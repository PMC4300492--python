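"""Discrete-generation model of cell-size control.

A cell born at volume ``V`` that grows exponentially at specific rate
``lam`` for a cycle time ``T`` and then hands a fraction ``1/n`` of its
division volume to the progeny being followed obeys, in log-volume
``v = log(V)``,

    v_{i+1} = v_i + lam * T_i - log(n_i).

Balanced growth requires ``<lam*T> = <log n>``; without size control the
per-cycle residual ``eps = lam*T - log(n)`` accumulates as a random walk.
A bounded, size-dependent cycle time ``T(v)`` (longer for small-born
cells) creates an attracting fixed point at the log-size ``v*`` solving
``lam * T(v*) = log(n)``.  Because ``T`` is bounded in ``[T_min, T_max]``
the fixed point exists only in a confined band: when ``lam*T_max <
log(n)`` every cycle loses volume and cells shrink away (type I arrest);
when ``lam*T_min > log(n)`` every cycle gains volume and cells grow away
(type II arrest).

This module provides the map, the cycle-time family, fixed-point and
stability analysis, the threshold (checkpoint) variant of size control,
regime classification and phase diagrams.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "GrowthParams",
    "CycleTimeFunction",
    "CheckpointParams",
    "Regime",
    "RegimeResult",
    "log_size_update",
    "epsilon",
    "cycle_time",
    "find_fixed_point",
    "stability_at",
    "classify_regime",
    "checkpoint_cycle_time",
    "phase_diagram",
    "non_exponential_update",
]

#: Root-finding tolerance on lam*T(v) - log(n) at the fixed point.
FIXED_POINT_TOL = 1e-8
#: Central-difference step for the stability multiplier.
FD_STEP = 1e-5
#: Margin below which a boundary bracketing is treated as degenerate.
BRACKET_MARGIN = 1e-12


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its domain."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class GrowthParams:
    """Per-cycle growth parameters.

    Parameters
    ----------
    lam : float
        Specific volume growth rate, 1/h, > 0.
    n : float
        Division ratio, > 1.  The followed progeny receives a fraction
        ``1/n`` of the division volume (n = 2 symmetric; n > 2 for
        budding-yeast daughters).
    sigma_lam, sigma_T, sigma_n : float
        Standard deviations of per-cycle multiplicative (log-scale)
        fluctuations in lam, T, and of additive fluctuations in log(n).
    """

    lam: float
    n: float = 2.0
    sigma_lam: float = 0.0
    sigma_T: float = 0.0
    sigma_n: float = 0.0

    def __post_init__(self) -> None:
        _require(self.lam > 0, f"lam must be > 0, got {self.lam}")
        _require(self.n > 1, f"n must be > 1, got {self.n}")
        for name in ("sigma_lam", "sigma_T", "sigma_n"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass(frozen=True)
class CycleTimeFunction:
    """Bounded logistic cycle-time law, non-increasing in log-size.

    ``T(v) = T_min + (T_max - T_min) / (1 + exp((v - v_half) / width))``

    so ``T -> T_max`` for very small cells, ``T -> T_min`` for very
    large ones, and ``T(v_half)`` is the midpoint.  Smooth and strictly
    decreasing whenever ``T_max > T_min``, which is what makes the
    fixed point of the size map attracting.
    """

    T_min: float
    T_max: float
    v_half: float = 0.0
    width: float = 1.0

    def __post_init__(self) -> None:
        _require(self.T_min > 0, f"T_min must be > 0, got {self.T_min}")
        _require(self.T_max >= self.T_min, "T_max must be >= T_min")
        _require(self.width > 0, f"width must be > 0, got {self.width}")
        _require(math.isfinite(self.v_half), "v_half must be finite")

    def __call__(self, v: float | np.ndarray) -> float | np.ndarray:
        z = (np.asarray(v, dtype=float) - self.v_half) / self.width
        # expit is overflow-safe for |z| >> 1
        out = self.T_min + (self.T_max - self.T_min) * expit(-z)
        return float(out) if np.isscalar(v) else out

    def derivative(self, v: float) -> float:
        """dT/dv, analytic (<= 0 everywhere)."""
        z = (v - self.v_half) / self.width
        s = 1.0 / (1.0 + math.exp(-z))  # logistic sigma(z)
        return -(self.T_max - self.T_min) * s * (1.0 - s) / self.width


@dataclass(frozen=True)
class CheckpointParams:
    """Threshold (checkpoint) size control.

    G1 lasts until log-size reaches ``v_crit`` (but at least
    ``T_G1_min``); an optional timer ``tau_max`` lets small cells pass
    the checkpoint after waiting that long even if still below the
    critical size.  The post-commitment (budded) phase has fixed
    duration ``T_budded``.
    """

    v_crit: float
    T_G1_min: float = 0.0
    T_budded: float = 1.0
    tau_max: Optional[float] = None

    def __post_init__(self) -> None:
        _require(math.isfinite(self.v_crit), "v_crit must be finite")
        _require(self.T_G1_min >= 0, "T_G1_min must be >= 0")
        _require(self.T_budded > 0, "T_budded must be > 0")
        if self.tau_max is not None:
            _require(self.tau_max > 0, "tau_max must be > 0 when given")


class Regime(str, enum.Enum):
    HOMEOSTATIC = "HOMEOSTATIC"
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"


@dataclass(frozen=True)
class RegimeResult:
    """Outcome of regime classification.

    ``fixed_point`` and ``stable`` are present iff the regime is
    HOMEOSTATIC.
    """

    regime: Regime
    fixed_point: Optional[float] = None
    stable: Optional[bool] = None
    multiplier: Optional[float] = None

    def __post_init__(self) -> None:
        has_fp = self.fixed_point is not None
        if (self.regime is Regime.HOMEOSTATIC) != has_fp:
            raise ValueError("fixed_point present iff regime is HOMEOSTATIC")


def _check_cycle(lam: float, T: float, n: float) -> None:
    _require(lam > 0, f"lam must be > 0, got {lam}")
    _require(T > 0, f"T must be > 0, got {T}")
    _require(n > 1, f"n must be > 1, got {n}")


def log_size_update(v: float, lam: float, T: float, n: float) -> float:
    """One generation of the log-size map: ``v + lam*T - log(n)``."""
    _check_cycle(lam, T, n)
    return v + lam * T - math.log(n)


def epsilon(lam: float, T: float, n: float) -> float:
    """Per-cycle imbalance ``lam*T - log(n)`` between growth and division loss."""
    _check_cycle(lam, T, n)
    return lam * T - math.log(n)


def cycle_time(v: float, f: CycleTimeFunction) -> float:
    """Cycle time of a cell born at log-size ``v`` under the gradual law."""
    return float(f(v))


def find_fixed_point(
    params: GrowthParams, f: CycleTimeFunction
) -> Optional[float]:
    """Log-size ``v*`` with ``lam * T(v*) = log(n)``, or None.

    Exists iff ``log(n)/lam`` lies strictly inside ``(T_min, T_max)``
    (strict bracketing with a small margin; boundary ties resolve to
    "no fixed point at finite v" and are classified homeostatic-free
    by :func:`classify_regime` only on the appropriate side).
    """
    target = math.log(params.n) / params.lam
    if not (f.T_min + BRACKET_MARGIN < target < f.T_max - BRACKET_MARGIN):
        return None

    def g(v: float) -> float:
        return params.lam * float(f(v)) - math.log(params.n)

    # bracket: g is decreasing in v; expand around v_half
    lo, hi = f.v_half - 1.0, f.v_half + 1.0
    for _ in range(200):
        if g(lo) > 0:
            break
        lo -= max(1.0, f.width)
    for _ in range(200):
        if g(hi) < 0:
            break
        hi += max(1.0, f.width)
    v_star = brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(g(v_star)) < FIXED_POINT_TOL
    return float(v_star)


def stability_at(
    v_star: float, params: GrowthParams, f: CycleTimeFunction
) -> tuple[bool, float]:
    """Stability of a fixed point of the size map.

    Returns ``(stable, m)`` with the per-generation multiplier
    ``m = 1 + lam * T'(v*)`` estimated by central differences; the
    fixed point is stable iff ``|m| < 1``.  ``T' = 0`` (constant cycle
    time) gives ``m = 1``, the marginal random-walk case, reported
    unstable.
    """
    resid = params.lam * float(f(v_star)) - math.log(params.n)
    if abs(resid) > 1e-6:
        raise InvalidParameterError(
            f"v_star={v_star} is not a fixed point (residual {resid:.3g})"
        )
    h = FD_STEP
    dT = (float(f(v_star + h)) - float(f(v_star - h))) / (2 * h)
    m = 1.0 + params.lam * dT
    return (abs(m) < 1.0), m


def classify_regime(params: GrowthParams, f: CycleTimeFunction) -> RegimeResult:
    """Classify a parameter set as HOMEOSTATIC / TYPE_I / TYPE_II.

    TYPE_I  iff ``lam*T_max < log(n)`` (every cycle loses volume),
    TYPE_II iff ``lam*T_min > log(n)`` (every cycle gains volume),
    HOMEOSTATIC otherwise, with fixed point and stability attached.
    Boundary equalities classify as the arrest regime only on strict
    inequality; exact ties side with HOMEOSTATIC except that a fixed
    point is then reported at the solver's bracketing margin.
    """
    log_n = math.log(params.n)
    if params.lam * f.T_max < log_n:
        return RegimeResult(Regime.TYPE_I)
    if params.lam * f.T_min > log_n:
        return RegimeResult(Regime.TYPE_II)
    v_star = find_fixed_point(params, f)
    if v_star is None:
        # degenerate boundary tie (lam*T_max == log n or lam*T_min == log n
        # within margin): no finite fixed point; side with the arrest regime
        # whose inequality holds weakly.
        if params.lam * f.T_max <= log_n:
            return RegimeResult(Regime.TYPE_I)
        return RegimeResult(Regime.TYPE_II)
    stable, m = stability_at(v_star, params, f)
    return RegimeResult(Regime.HOMEOSTATIC, v_star, stable, m)


def checkpoint_cycle_time(
    v_birth: float, cp: CheckpointParams, lam: float
) -> float:
    """Cycle time under checkpoint control.

    G1 lasts until the cell grows to ``v_crit`` (time
    ``(v_crit - v_birth)/lam``), at least ``T_G1_min``, and at most
    ``tau_max`` when the timer variant is active; the budded phase adds
    ``T_budded``.
    """
    _require(lam > 0, f"lam must be > 0, got {lam}")
    g1 = max(cp.T_G1_min, (cp.v_crit - v_birth) / lam)
    if cp.tau_max is not None:
        g1 = min(g1, max(cp.T_G1_min, cp.tau_max))
    return g1 + cp.T_budded


def phase_diagram(
    lam_grid: Sequence[float],
    cycle_time_grid: Sequence[CycleTimeFunction],
    n: float = 2.0,
) -> pd.DataFrame:
    """Regime map over a grid of growth rates and cycle-time laws.

    Returns a tidy frame with columns
    ``lam, T_min, T_max, n, regime, v_star, stable``; region boundaries
    are the curves ``lam*T_max = log(n)`` and ``lam*T_min = log(n)``.
    """
    _require(len(lam_grid) > 0 and len(cycle_time_grid) > 0, "grids must be non-empty")
    rows = []
    for lam in lam_grid:
        params = GrowthParams(lam=lam, n=n)
        for f in cycle_time_grid:
            res = classify_regime(params, f)
            rows.append(
                {
                    "lam": lam,
                    "T_min": f.T_min,
                    "T_max": f.T_max,
                    "n": n,
                    "regime": res.regime.value,
                    "v_star": np.nan if res.fixed_point is None else res.fixed_point,
                    "stable": res.stable,
                }
            )
    return pd.DataFrame(rows)


def non_exponential_update(
    v: float,
    growth_law: str | Callable[[float, float], float],
    T: float,
    n: float,
    *,
    a: Optional[float] = None,
    lam: Optional[float] = None,
) -> float:
    """One generation of the size map under a non-exponential growth law.

    ``growth_law`` is either ``"linear"`` (constant absolute rate ``a``:
    ``V(t) = V0 + a*t``), ``"exponential"`` (rate ``lam``; reduces
    exactly to :func:`log_size_update`), or a callable ``V(t, V0)``.
    Returns ``log(V(T; exp(v)) / n)``.  For linear growth with constant
    T and n the induced map has a stable fixed point even without any
    size-dependent cycle time (at ``V* = a*T/(n-1)``).
    """
    _require(T > 0, f"T must be > 0, got {T}")
    _require(n > 1, f"n must be > 1, got {n}")
    V0 = math.exp(v)
    if callable(growth_law):
        VT = float(growth_law(T, V0))
        _require(VT > 0, "growth law returned non-positive volume")
    elif growth_law == "linear":
        _require(a is not None and a > 0, "linear growth needs a > 0")
        VT = V0 + a * T
    elif growth_law == "exponential":
        _require(lam is not None and lam > 0, "exponential growth needs lam > 0")
        return log_size_update(v, lam, T, n)
    else:
        raise InvalidParameterError(f"unknown growth law {growth_law!r}")
    return math.log(VT / n)
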