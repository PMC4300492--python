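"""Growth-parameter extraction from single-cell tracking tables.

Re-implements the standard microfluidics quantification chain: per-colony
growth curves (cell counts over time), division rate as the OLS slope of
log2 counts versus time, time-resolved mean cell size with a 2-hour
minimum-age rule (so newborn buds that have not reached final size do
not drag the mean down), a steady-state test (divisions continuing and a
flat size trend in the final window), and arrest-type classification
(small-cell type I versus large-cell type II) with the number of
divisions sustained before arrest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import InvalidParameterError

__all__ = [
    "GrowthSummary",
    "colony_growth_curve",
    "division_rate",
    "mean_cell_size",
    "steady_state_test",
    "classify_arrest",
    "classify_arrest_table",
    "size_rate_correlation",
    "quantify_table",
]

#: Buds need time to reach final size; exclude cells younger than this.
MIN_AGE_H = 2.0
#: Default steady-state tolerance on the relative size slope, per hour.
STEADY_SLOPE_TOL = 0.02
#: Arrest size thresholds relative to the early-steady mean.
THETA_I = 0.7
THETA_II = 1.5
#: No divisions within this final window -> arrested.
ARREST_WINDOW_H = 5.0


@dataclass
class GrowthSummary:
    """Quantification output for one colony (or an aggregate)."""

    division_rate: float
    rate_window: tuple[float, float]
    rate_r2: float
    size_timecourse: pd.DataFrame  # time_h, mean_size_fL, n_cells
    steady_state: bool
    arrest_call: str  # STEADY | TYPE_I | TYPE_II | INDETERMINATE
    divisions_to_arrest: Optional[float] = None

    def __post_init__(self) -> None:
        if self.division_rate < 0 and not math.isnan(self.division_rate):
            raise InvalidParameterError("division_rate must be >= 0")
        if self.arrest_call == "STEADY" and not self.steady_state:
            raise InvalidParameterError("STEADY call requires steady_state")


def _check_schema(table: pd.DataFrame) -> None:
    missing = {"time_h", "cell_id", "size_fL"} - set(table.columns)
    if missing:
        raise InvalidParameterError(f"tracking table lacks columns {sorted(missing)}")


def colony_growth_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Cell counts per frame, per colony.

    Returns a tidy frame ``position, colony, time_h, n_cells`` (counts
    are non-decreasing in time: cells persist once born).
    """
    _check_schema(table)
    df = table.copy()
    for col in ("position", "colony"):
        if col not in df.columns:
            df[col] = 0
    out = (
        df.groupby(["position", "colony", "time_h"])["cell_id"]
        .nunique()
        .rename("n_cells")
        .reset_index()
        .sort_values(["position", "colony", "time_h"])
        .reset_index(drop=True)
    )
    return out


def division_rate(
    counts: pd.DataFrame | Sequence[float],
    window: Optional[tuple[float, float]] = None,
    times: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Division rate (1/h) as the OLS slope of log2 N(t), with R^2.

    Accepts a ``time_h``/``n_cells`` frame or parallel sequences.  With
    a constant count the rate is 0 and R^2 is NaN.
    """
    if isinstance(counts, pd.DataFrame):
        t = counts["time_h"].to_numpy(float)
        N = counts["n_cells"].to_numpy(float)
    else:
        N = np.asarray(counts, float)
        t = np.asarray(times, float)
    keep = N > 0
    if window is not None:
        keep &= (t >= window[0]) & (t <= window[1])
    t, N = t[keep], N[keep]
    if len(t) < 3:
        raise InvalidParameterError("need >= 3 positive counts in window")
    y = np.log2(N)
    if np.ptp(y) == 0:
        return 0.0, float("nan")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.rvalue**2)


def _birth_times(table: pd.DataFrame) -> pd.Series:
    """Birth time per cell = first frame in which it appears."""
    return table.groupby("cell_id")["time_h"].min()


def mean_cell_size(
    table: pd.DataFrame, t: float, min_age_h: float = MIN_AGE_H
) -> tuple[Optional[float], int]:
    """Mean size (fL) at frame ``t`` over cells born >= ``min_age_h`` earlier.

    Returns ``(mean, count)``; the mean is None when no cell qualifies.
    """
    _check_schema(table)
    birth = _birth_times(table)
    frame = table[np.isclose(table["time_h"], t)]
    if frame.empty:
        raise InvalidParameterError(f"no frame at t={t}")
    old = frame["cell_id"].map(birth) <= t - min_age_h
    sizes = frame.loc[old, "size_fL"]
    if sizes.empty:
        return None, 0
    return float(sizes.mean()), int(sizes.size)


def size_timecourse(
    table: pd.DataFrame, min_age_h: float = MIN_AGE_H
) -> pd.DataFrame:
    """Mean mature-cell size per frame (vectorised across frames)."""
    _check_schema(table)
    birth = _birth_times(table)
    df = table.copy()
    df["birth"] = df["cell_id"].map(birth)
    df = df[df["birth"] <= df["time_h"] - min_age_h]
    out = (
        df.groupby("time_h")["size_fL"]
        .agg(mean_size_fL="mean", n_cells="size")
        .reset_index()
    )
    return out


def steady_state_test(
    counts: pd.DataFrame,
    sizes: pd.DataFrame,
    window_h: float = 4.0,
    slope_tol: float = STEADY_SLOPE_TOL,
) -> bool:
    """Steady iff divisions continue and mean size is flat, late in the run.

    Over the final ``window_h``: (a) the cell count must increase, and
    (b) the OLS slope of mean size versus time, relative to the window
    mean size, must be within ``slope_tol`` (default 2%/h) of zero.
    """
    if window_h < 4.0:
        raise InvalidParameterError("window_h must be >= 4 h")
    t_end = float(counts["time_h"].max())
    w0 = t_end - window_h
    cw = counts[counts["time_h"] >= w0]
    if cw["n_cells"].iloc[-1] <= cw["n_cells"].iloc[0]:
        return False
    sw = sizes[(sizes["time_h"] >= w0) & sizes["mean_size_fL"].notna()]
    if len(sw) < 3:
        return False
    res = stats.linregress(sw["time_h"], sw["mean_size_fL"])
    rel = res.slope / sw["mean_size_fL"].mean()
    return bool(abs(rel) <= slope_tol)


def _generation_depth(table: pd.DataFrame) -> pd.Series:
    """Number of ancestor divisions per cell, from parent_id links."""
    parents = (
        table.groupby("cell_id")["parent_id"].first()
        if "parent_id" in table.columns
        else pd.Series(dtype=int)
    )
    depth: dict[int, int] = {}

    def get(cid: int) -> int:
        chain = []
        while cid not in depth:
            chain.append(cid)
            par = int(parents.get(cid, -1))
            if par < 0:
                depth[cid] = 0
                break
            cid = par
        for c in reversed(chain):
            if c not in depth:
                depth[c] = depth[int(parents[c])] + 1
        return depth[chain[0]] if chain else depth[cid]

    return pd.Series({cid: get(int(cid)) for cid in parents.index})


def classify_arrest(
    table: pd.DataFrame,
    steady_window_h: float = 4.0,
    arrest_window_h: float = ARREST_WINDOW_H,
    theta_I: float = THETA_I,
    theta_II: float = THETA_II,
    early_window: tuple[float, float] = (3.0, 9.0),
) -> GrowthSummary:
    """Classify one colony's table as STEADY / TYPE_I / TYPE_II / INDETERMINATE.

    Steady colonies pass :func:`steady_state_test`.  Otherwise, a colony
    with no division in the final ``arrest_window_h`` is arrested; the
    call is TYPE_I when the terminal mean size fell below ``theta_I``
    times the early reference mean, TYPE_II when it exceeds ``theta_II``
    times it, INDETERMINATE in between (or when divisions are still
    ongoing but size drifts).
    """
    _check_schema(table)
    t0, t1 = float(table["time_h"].min()), float(table["time_h"].max())
    if t1 - t0 < 10.0:
        raise InvalidParameterError("table must span >= 10 h")
    counts = colony_growth_curve(table)[["time_h", "n_cells"]]
    counts = counts.groupby("time_h", as_index=False)["n_cells"].sum()
    sizes = size_timecourse(table)

    burn_in = counts.loc[counts["n_cells"] >= 4, "time_h"]
    fit_start = float(burn_in.iloc[0]) if len(burn_in) else t0
    try:
        rate, r2 = division_rate(counts, window=(fit_start, t1))
    except InvalidParameterError:
        rate, r2 = division_rate(counts)
    rate = max(rate, 0.0)

    steady = steady_state_test(counts, sizes, window_h=steady_window_h)
    if steady:
        return GrowthSummary(rate, (fit_start, t1), r2, sizes, True, "STEADY")

    aw = counts[counts["time_h"] >= t1 - arrest_window_h]
    divisions_stopped = aw["n_cells"].iloc[-1] <= aw["n_cells"].iloc[0]

    early = sizes[(sizes["time_h"] >= early_window[0])
                  & (sizes["time_h"] <= early_window[1])]
    terminal = sizes[sizes["time_h"] >= t1 - 1.0]
    call = "INDETERMINATE"
    if divisions_stopped and len(early) and len(terminal):
        ref = float(early["mean_size_fL"].mean())
        term = float(terminal["mean_size_fL"].mean())
        if term < theta_I * ref:
            call = "TYPE_I"
        elif term > theta_II * ref:
            call = "TYPE_II"
    div_to_arrest = None
    if divisions_stopped and "parent_id" in table.columns:
        div_to_arrest = float(_generation_depth(table).mean())
    return GrowthSummary(rate, (fit_start, t1), r2, sizes, False, call,
                         div_to_arrest)


def classify_arrest_table(table: pd.DataFrame, **kwargs) -> tuple[str, list[GrowthSummary]]:
    """Classify every colony in a multi-colony table; majority vote.

    Ties resolve in the order STEADY, TYPE_II, TYPE_I, INDETERMINATE.
    """
    _check_schema(table)
    df = table.copy()
    for col in ("position", "colony"):
        if col not in df.columns:
            df[col] = 0
    summaries = []
    for _, sub in df.groupby(["position", "colony"]):
        try:
            summaries.append(classify_arrest(sub, **kwargs))
        except InvalidParameterError:
            continue
    if not summaries:
        raise InvalidParameterError("no colony spans >= 10 h")
    calls = pd.Series([s.arrest_call for s in summaries])
    order = ["STEADY", "TYPE_II", "TYPE_I", "INDETERMINATE"]
    counts = calls.value_counts()
    best = max(order, key=lambda c: (counts.get(c, 0), -order.index(c)))
    return best, summaries


def size_rate_correlation(
    sizes: Sequence[float], rates: Sequence[float]
) -> tuple[Optional[int], float]:
    """Spearman rank correlation of steady-state size versus division rate.

    Returns ``(sign, rho)``; sign is None when the correlation is
    undefined (fewer than 3 points or constant inputs).
    """
    s = np.asarray(sizes, float)
    r = np.asarray(rates, float)
    if len(s) < 3 or np.ptp(s) == 0 or np.ptp(r) == 0:
        return None, float("nan")
    rho = stats.spearmanr(s, r).statistic
    return int(np.sign(rho)), float(rho)


def quantify_table(table: pd.DataFrame, **kwargs) -> dict:
    """One-call summary used by the command-line interface."""
    call, summaries = classify_arrest_table(table, **kwargs)
    rates = [s.division_rate for s in summaries]
    steadies = [s.steady_state for s in summaries]
    terminal_sizes = [
        float(s.size_timecourse["mean_size_fL"].iloc[-1])
        for s in summaries if len(s.size_timecourse)
    ]
    d2a = [s.divisions_to_arrest for s in summaries
           if s.divisions_to_arrest is not None]
    return {
        "arrest_call": call,
        "n_colonies": len(summaries),
        "division_rate_per_h": float(np.mean(rates)),
        "steady_fraction": float(np.mean(steadies)),
        "terminal_mean_size_fL": (
            float(np.mean(terminal_sizes)) if terminal_sizes else None
        ),
        "divisions_to_arrest": float(np.mean(d2a)) if d2a else None,
        "colony_rates_per_h": [float(r) for r in rates],
        "colony_calls": [s.arrest_call for s in summaries],
    }
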