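"""Seeded end-to-end regime benchmark: generator -> quantification.

Runs the synthetic microfluidics generator across the full condition
panel (wild-type glucose series, transporterless glucose series with and
without sensors, and dox-titrated single-transporter series at fixed
0.1% glucose), quantifies every run blind to its ground truth, and
scores regime calls plus the size/rate correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .physiology import Condition, PhysiologyParams, expected_regime, \
    generate_tracking_table
from .quantify import classify_arrest_table, size_rate_correlation

__all__ = ["BenchmarkRun", "benchmark_conditions", "run_benchmark"]

WT_GLUCOSE = (0.01, 0.05, 0.1, 0.5, 2.0)
TLESS_GLUCOSE = (0.01, 0.1, 0.5, 2.0)
DOX_STEADY = (250.0, 500.0, 1000.0, 2000.0, 4000.0)


@dataclass
class BenchmarkRun:
    condition: Condition
    seed: int
    truth: str
    call: Optional[str] = None
    division_rate: Optional[float] = None
    steady_size: Optional[float] = None
    terminal_size: Optional[float] = None
    divisions_to_arrest: Optional[float] = None


def benchmark_conditions(p: PhysiologyParams) -> list[tuple[Condition, int]]:
    """The 60-run condition x seed-replicate panel."""
    runs: list[tuple[Condition, int]] = []

    def add(cond: Condition, n_rep: int) -> None:
        for rep in range(n_rep):
            runs.append((cond, rep))

    for g in WT_GLUCOSE:
        add(Condition("WT", glucose_pct=g), 2)
    for g in (0.01, 0.1, 2.0):
        add(Condition("WT", glucose_pct=g), 1)
    for g in TLESS_GLUCOSE:
        add(Condition("transporterless", glucose_pct=g), 3)
    for g in (0.01, 0.1, 2.0):
        add(Condition("transporterless_sensorless", glucose_pct=g), 3)
    for dox in (0.0, 60.0):
        add(Condition("single_HXT", glucose_pct=0.1, dox_ng_ml=dox), 2)
    for dox in DOX_STEADY:
        add(Condition("single_HXT", glucose_pct=0.1, dox_ng_ml=dox), 2)
    add(Condition("single_HXT_sensorless", glucose_pct=0.1, dox_ng_ml=0.0), 2)
    for dox in DOX_STEADY:
        add(Condition("single_HXT_sensorless", glucose_pct=0.1, dox_ng_ml=dox), 2)
    assert len(runs) == 60
    return runs


def _steady_size(summaries, window_h: float = 4.0) -> Optional[float]:
    """Mean mature-cell size over each steady colony's final window."""
    vals = []
    for s in summaries:
        if s.arrest_call != "STEADY":
            continue
        tc = s.size_timecourse
        t1 = tc["time_h"].max()
        vals.append(float(tc.loc[tc["time_h"] >= t1 - window_h,
                                 "mean_size_fL"].mean()))
    return float(np.mean(vals)) if vals else None


def _run_one(cond: Condition, p: PhysiologyParams, seed: int,
             duration_h: float, max_cells: int, n_positions: int
             ) -> BenchmarkRun:
    table = generate_tracking_table(
        cond, p, seed=seed, duration_h=duration_h,
        n_positions=n_positions, max_cells_per_colony=max_cells,
    )
    call, summaries = classify_arrest_table(table)
    steady = [s for s in summaries if s.arrest_call == "STEADY"]
    rates = [s.division_rate for s in (steady if steady else summaries)]
    term = [
        float(s.size_timecourse["mean_size_fL"].iloc[-1])
        for s in summaries if len(s.size_timecourse)
    ]
    d2a = [s.divisions_to_arrest for s in summaries
           if s.divisions_to_arrest is not None]
    return BenchmarkRun(
        condition=cond,
        seed=seed,
        truth=expected_regime(cond, p),
        call=call,
        division_rate=float(np.mean(rates)) if rates else None,
        steady_size=_steady_size(summaries),
        terminal_size=float(np.mean(term)) if term else None,
        divisions_to_arrest=float(np.mean(d2a)) if d2a else None,
    )


def _condition_mean(runs: list[BenchmarkRun], attr: str) -> dict[tuple, float]:
    """Seed-replicate averages keyed by (genotype, glucose, dox)."""
    acc: dict[tuple, list[float]] = {}
    for r in runs:
        key = (r.condition.genotype, r.condition.glucose_pct,
               r.condition.dox_ng_ml)
        val = getattr(r, attr)
        if val is not None and np.isfinite(val):
            acc.setdefault(key, []).append(val)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def run_benchmark(
    seed: int = 0,
    p: PhysiologyParams | None = None,
    duration_h: float = 34.0,
    max_cells: int = 1500,
    n_positions: int = 2,
) -> dict:
    """Execute the 60-run panel and score it.

    Returns a dict with per-run results and the headline metrics:
    arrest-call accuracy against the analytic ground truth, the
    wild-type glucose-series correlations, the transporterless
    monotonicity checks, and the dox-series size/rate Spearman
    correlations with and without sensors.
    """
    if p is None:
        p = PhysiologyParams()
    panel = benchmark_conditions(p)
    runs: list[BenchmarkRun] = []
    for i, (cond, rep) in enumerate(panel):
        run_seed = (seed * 100003 + i * 1009 + rep) % (2**31 - 1)
        runs.append(_run_one(cond, p, run_seed, duration_h, max_cells,
                             n_positions))

    n_correct = sum(1 for r in runs if r.call == r.truth)
    accuracy = 100.0 * n_correct / len(runs)

    rate_by = _condition_mean(runs, "division_rate")
    ssize_by = _condition_mean(runs, "steady_size")
    term_by = _condition_mean(runs, "terminal_size")
    d2a_by = _condition_mean(runs, "divisions_to_arrest")

    def series(genotype: str, glucose: list[float] | None = None,
               dox: list[float] | None = None, table: dict = ssize_by):
        out = []
        if glucose is not None:
            keys = [(genotype, g, 0.0) for g in glucose]
        else:
            keys = [(genotype, 0.1, d) for d in dox]
        for k in keys:
            out.append(table.get(k))
        return out

    wt_sizes = series("WT", glucose=list(WT_GLUCOSE))
    wt_rates = series("WT", glucose=list(WT_GLUCOSE), table=rate_by)
    _, wt_rho = size_rate_correlation(
        [s for s in wt_sizes if s], [r for s, r in zip(wt_sizes, wt_rates) if s]
    )

    dox = list(DOX_STEADY)
    sens_sizes = series("single_HXT", dox=dox)
    sens_rates = series("single_HXT", dox=dox, table=rate_by)
    _, sens_rho = size_rate_correlation(
        [s for s in sens_sizes if s],
        [r for s, r in zip(sens_sizes, sens_rates) if s],
    )
    nos_sizes = series("single_HXT_sensorless", dox=dox)
    nos_rates = series("single_HXT_sensorless", dox=dox, table=rate_by)
    _, nos_rho = size_rate_correlation(
        [s for s in nos_sizes if s],
        [r for s, r in zip(nos_sizes, nos_rates) if s],
    )

    t2_glucose = [0.1, 0.5, 2.0]
    t2_term = [term_by.get(("transporterless", g, 0.0)) for g in t2_glucose]
    t2_d2a = [d2a_by.get(("transporterless", g, 0.0))
              for g in [0.01, 0.1, 0.5, 2.0]]

    return {
        "runs": runs,
        "n_runs": len(runs),
        "accuracy_pct": accuracy,
        "wt_size_rate_spearman": wt_rho,
        "wt_sizes_fL": wt_sizes,
        "wt_rates_per_h": wt_rates,
        "dox_spearman_sensors": sens_rho,
        "dox_spearman_sensorless": nos_rho,
        "dox_sizes_sensors": sens_sizes,
        "dox_rates_sensors": sens_rates,
        "dox_sizes_sensorless": nos_sizes,
        "dox_rates_sensorless": nos_rates,
        "typeII_terminal_sizes_fL": t2_term,
        "typeII_divisions_to_arrest": t2_d2a,
    }
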