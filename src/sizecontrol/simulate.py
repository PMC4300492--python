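"""Stochastic multi-generation lineage and pedigree simulation.

Cells grow exponentially within a cycle and divide asymmetrically: a
divider of log-size ``v_end`` produces a daughter of log-size
``v_end - log(n)`` while the mother keeps ``v_end + log(1 - 1/n)``, so
volume is conserved exactly at every division.  The cycle time is set by
the chosen size-control mechanism (constant, gradual ``T(v)``, or
checkpoint), per-cycle noise is multiplicative log-scale on ``lam`` and
``T`` and additive on ``log n``, and a cycle whose computed time exceeds
``T_cap`` is recorded as ARRESTED.  Events are scheduled on a
deterministic queue ordered by (time, cell id), so a fixed seed
reproduces the event table bit for bit.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .models import (
    CheckpointParams,
    CycleTimeFunction,
    GrowthParams,
    InvalidParameterError,
    checkpoint_cycle_time,
)

__all__ = [
    "CellCycleRecord",
    "SimulationConfig",
    "Mechanism",
    "simulate_lineage",
    "simulate_population",
    "simulate_random_walk_ensemble",
    "records_to_table",
    "table_to_records",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = [
    "cell_id",
    "parent_id",
    "cycle_index",
    "t_start_h",
    "t_end_h",
    "v_start",
    "v_end",
    "lam",
    "T_h",
    "n",
    "outcome",
]

#: Mechanism: None for a constant cycle time, a CycleTimeFunction for
#: gradual size control, a CheckpointParams for threshold control, or a
#: callable (v_birth, t_birth, lam) -> T for externally driven physiology.
Mechanism = Union[
    None, CycleTimeFunction, CheckpointParams, Callable[[float, float, float], float]
]


@dataclass(frozen=True)
class CellCycleRecord:
    """One cell cycle: birth to division / arrest / censoring."""

    cell_id: int
    parent_id: Optional[int]
    cycle_index: int
    t_start: float
    t_end: float
    v_start: float
    v_end: float
    lam_i: float
    T_i: float
    n_i: float
    outcome: str  # DIVIDED | ARRESTED | CENSORED


@dataclass(frozen=True)
class SimulationConfig:
    """Population-simulation controls.

    ``T_const`` is the constant cycle time used when no size-dependent
    mechanism is supplied.  A computed cycle time above ``T_cap``
    (default 20 h, i.e. no division within a typical experiment) marks
    the cell ARRESTED rather than scheduling an implausible division.
    """

    seed: int = 0
    t_max: float = 24.0
    max_cells: int = 1000
    T_const: float = 2.0
    T_cap: float = 20.0
    v0: float = math.log(30.0)

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise InvalidParameterError("t_max must be > 0")
        if self.max_cells < 1:
            raise InvalidParameterError("max_cells must be >= 1")
        if self.T_cap <= 0:
            raise InvalidParameterError("T_cap must be > 0")
        if self.T_const <= 0:
            raise InvalidParameterError("T_const must be > 0")


def _deterministic_T(
    v: float, t: float, lam: float, mechanism: Mechanism, T_const: float
) -> float:
    if mechanism is None:
        return T_const
    if isinstance(mechanism, CycleTimeFunction):
        return float(mechanism(v))
    if isinstance(mechanism, CheckpointParams):
        return checkpoint_cycle_time(v, mechanism, lam)
    return float(mechanism(v, t, lam))


def _draw_cycle(
    rng: np.random.Generator,
    params: GrowthParams,
    T_det: float,
    lam_base: Optional[float] = None,
) -> tuple[float, float, float]:
    """Realized (lam_i, T_i, n_i) with truncated log-scale noise."""
    lam0 = params.lam if lam_base is None else lam_base
    lam_i = lam0 * math.exp(params.sigma_lam * rng.standard_normal()) \
        if params.sigma_lam > 0 else lam0
    T_i = T_det * math.exp(params.sigma_T * rng.standard_normal()) \
        if params.sigma_T > 0 else T_det
    if params.sigma_n > 0:
        log_n = math.log(params.n) + params.sigma_n * rng.standard_normal()
        n_i = math.exp(max(log_n, 1e-6))  # keep n > 1
    else:
        n_i = params.n
    return lam_i, T_i, n_i


def simulate_lineage(
    v0: float,
    params: GrowthParams,
    mechanism: Mechanism = None,
    k: int = 10,
    seed: int = 0,
    T_const: float = 2.0,
    T_cap: float = math.inf,
) -> list[CellCycleRecord]:
    """Follow the daughter line for ``k`` generations.

    With zero noise and a constant cycle time this reduces to the
    closed form ``v_k = v0 + k * (lam*T - log n)``.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[CellCycleRecord] = []
    v, t = float(v0), 0.0
    for i in range(k):
        T_det = _deterministic_T(v, t, params.lam, mechanism, T_const)
        lam_i, T_i, n_i = _draw_cycle(rng, params, T_det)
        if T_i > T_cap:
            records.append(
                CellCycleRecord(i, None if i == 0 else i - 1, i, t, t + T_i,
                                v, v + lam_i * T_i, lam_i, T_i, n_i, "ARRESTED")
            )
            break
        v_end = v + lam_i * T_i
        records.append(
            CellCycleRecord(i, None if i == 0 else i - 1, i, t, t + T_i,
                            v, v_end, lam_i, T_i, n_i, "DIVIDED")
        )
        v = v_end - math.log(n_i)  # daughter
        t += T_i
    return records


def simulate_population(
    config: SimulationConfig,
    params: GrowthParams,
    mechanism: Mechanism = None,
    n_founders: int = 1,
    lam_t: Optional[Callable[[float], float]] = None,
) -> pd.DataFrame:
    """Simulate a full pedigree; both progeny of every division continue.

    Returns an event table (``EVENT_COLUMNS``).  The simulation stops at
    ``t_max`` or when ``max_cells`` distinct cells exist; cycles still
    open at the stop time are recorded CENSORED with the volume they
    have reached by then.  Volume is conserved exactly at division:
    ``exp(v_daughter) + exp(v_mother) = exp(v_end)``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[CellCycleRecord] = []
    next_id = 0
    # heap entries: (t_end, cell_id, cycle_index, parent_id, t_start, v_start,
    #                lam_i, T_i, n_i)
    heap: list = []
    n_cells = n_founders
    stopped = False
    stop_time = config.t_max

    def schedule(cell_id: int, parent_id: Optional[int], cycle_index: int,
                 t_start: float, v_start: float) -> None:
        lam_base = params.lam if lam_t is None else float(lam_t(t_start))
        T_det = _deterministic_T(v_start, t_start, lam_base, mechanism,
                                 config.T_const)
        lam_i, T_i, n_i = _draw_cycle(rng, params, T_det, lam_base)
        heapq.heappush(
            heap,
            (t_start + T_i, cell_id, cycle_index, parent_id, t_start, v_start,
             lam_i, T_i, n_i),
        )

    for _ in range(n_founders):
        schedule(next_id, None, 0, 0.0, config.v0)
        next_id += 1

    while heap:
        t_end, cell_id, cyc, parent_id, t_start, v_start, lam_i, T_i, n_i = \
            heapq.heappop(heap)
        if T_i > config.T_cap or t_end > stop_time:
            # a cycle that cannot complete within T_cap is an arrest;
            # one merely cut off by the observation end is censored
            outcome = "ARRESTED" if T_i > config.T_cap else "CENSORED"
            v_at_stop = v_start + lam_i * (stop_time - t_start)
            records.append(
                CellCycleRecord(cell_id, parent_id, cyc, t_start, stop_time,
                                v_start, v_at_stop, lam_i,
                                stop_time - t_start, n_i, outcome)
            )
            continue
        v_end = v_start + lam_i * T_i
        records.append(
            CellCycleRecord(cell_id, parent_id, cyc, t_start, t_end,
                            v_start, v_end, lam_i, T_i, n_i, "DIVIDED")
        )
        v_daughter = v_end - math.log(n_i)
        v_mother = v_end + math.log1p(-1.0 / n_i)
        # mother re-enters the cycle; daughter starts hers
        schedule(cell_id, parent_id, cyc + 1, t_end, v_mother)
        schedule(next_id, cell_id, 0, t_end, v_daughter)
        next_id += 1
        n_cells += 1
        if not stopped and n_cells >= config.max_cells:
            # device full: truncate observation here; open cycles censor
            stopped = True
            stop_time = t_end

    return records_to_table(records)


def simulate_random_walk_ensemble(
    n_lineages: int,
    k: int,
    sigma_eps: float,
    seed: int = 0,
    v0: float = 0.0,
) -> np.ndarray:
    """Pure random-walk log-size trajectories ``v_k = v0 + sum eps_i``.

    The no-size-control limit: balanced on average (``<eps> = 0``) but
    with per-cycle i.i.d. Gaussian imbalance of SD ``sigma_eps``, so the
    across-lineage variance grows linearly, ``Var(v_k) = k * sigma**2``.
    Returns an ``(n_lineages, k+1)`` array of full trajectories.
    """
    if n_lineages < 1:
        raise InvalidParameterError("n_lineages must be >= 1")
    if sigma_eps < 0:
        raise InvalidParameterError("sigma_eps must be >= 0")
    rng = np.random.default_rng(seed)
    eps = sigma_eps * rng.standard_normal((n_lineages, k))
    out = np.empty((n_lineages, k + 1))
    out[:, 0] = v0
    np.cumsum(eps, axis=1, out=out[:, 1:])
    out[:, 1:] += v0
    return out


def records_to_table(records: list[CellCycleRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "parent_id": [
                -1 if r.parent_id is None else r.parent_id for r in records
            ],
            "cycle_index": [r.cycle_index for r in records],
            "t_start_h": [r.t_start for r in records],
            "t_end_h": [r.t_end for r in records],
            "v_start": [r.v_start for r in records],
            "v_end": [r.v_end for r in records],
            "lam": [r.lam_i for r in records],
            "T_h": [r.T_i for r in records],
            "n": [r.n_i for r in records],
            "outcome": [r.outcome for r in records],
        }
    )
    return df.sort_values(["t_end_h", "cell_id", "cycle_index"]).reset_index(drop=True)


def table_to_records(df: pd.DataFrame) -> list[CellCycleRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            CellCycleRecord(
                int(row.cell_id),
                None if row.parent_id < 0 else int(row.parent_id),
                int(row.cycle_index),
                float(row.t_start_h),
                float(row.t_end_h),
                float(row.v_start),
                float(row.v_end),
                float(row.lam),
                float(row.T_h),
                float(row.n),
                str(row.outcome),
            )
        )
    return recs
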