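"""Synthetic microfluidics-data generator: glucose conditions -> growth.

Maps an experimental condition (genotype x external glucose x
doxycycline-titrated transporter induction) onto the size-control model
through a minimal influx/reserve bookkeeping, then runs the lineage
simulator and emits per-frame (10-min) tracking tables with pedigree,
emulating time-lapse imaging of colonies in a microfluidic device.

Mechanism (all coefficients live in :class:`PhysiologyParams`):

* Glucose influx is Michaelis-Menten in external glucose with a Vmax
  set by the genotype (wild type: full transporter complement;
  transporterless: zero; single-HXT: linear-in-dox ramp).
* The specific volume growth rate has a sensor-gated component driven
  by *external* glucose (Snf3/Rgt2 signalling; absent in sensorless
  genotypes), plus a substrate-limited component fed by influx and by
  an internal reserve pool.
* The reserve depletes at a rate proportional to the potential biomass
  demand; sensor-driven demand accelerates depletion, so high external
  glucose without matching influx exhausts the pool sooner.
* The cycle time is the gradual size-control law ``T(v)`` scaled by an
  influx speed-up (more influx, faster division machinery) and by a
  reserve-starvation multiplier that diverges as the pool empties,
  which is what ultimately arrests division.

This construction reproduces, qualitatively, steady wild-type growth
tracking glucose, type I (small-cell) arrest without influx or sensors,
type II (large-cell) arrest when sensor-driven growth outruns influx,
and the inverse size/division-rate correlation under dox titration at
fixed external glucose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import CycleTimeFunction, GrowthParams, InvalidParameterError
from .simulate import SimulationConfig, simulate_population

__all__ = [
    "Condition",
    "PhysiologyParams",
    "GENOTYPES",
    "glucose_pct_to_mM",
    "influx",
    "biomass_rate",
    "reserve_dynamics",
    "cycle_time_modifier",
    "condition_rates",
    "expected_regime",
    "generate_tracking_table",
    "TRACKING_COLUMNS",
]

TRACKING_COLUMNS = ["time_h", "position", "colony", "cell_id", "parent_id", "size_fL"]

GENOTYPES = (
    "WT",
    "transporterless",
    "transporterless_sensorless",
    "single_HXT",
    "single_HXT_sensorless",
)

#: grams per mole of glucose, for % w/v -> mM conversion.
GLUCOSE_MW = 180.16


def glucose_pct_to_mM(pct: float) -> float:
    """Convert % w/v glucose to mM (1% = 10 g/L = 55.5 mM)."""
    return pct * 10.0 / GLUCOSE_MW * 1000.0


@dataclass(frozen=True)
class Condition:
    """Genotype x external glucose x transporter induction."""

    genotype: str
    glucose_pct: float = 0.0
    dox_ng_ml: float = 0.0
    Km_mM: float = 10.0  # mid-affinity transporter (HXT2-like)
    sensors: Optional[bool] = None  # default: inferred from genotype

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise InvalidParameterError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if self.glucose_pct < 0:
            raise InvalidParameterError("glucose_pct must be >= 0")
        if self.dox_ng_ml < 0:
            raise InvalidParameterError("dox_ng_ml must be >= 0")
        if self.sensors is None:
            object.__setattr__(
                self, "sensors", not self.genotype.endswith("sensorless")
            )

    @property
    def glucose_mM(self) -> float:
        return glucose_pct_to_mM(self.glucose_pct)


@dataclass(frozen=True)
class PhysiologyParams:
    """Coefficients of the condition -> model-rate mapping.

    Rates are 1/h; the reserve is in flux-hour units per unit cell
    volume.  Defaults are calibrated once against the physiological
    anchors of the system being emulated: an influx-free division rate
    near 0.3/h, an influx-free growth transient of roughly 25 h, and a
    homeostatic band wide enough that wild type is steady from 0.01%
    to 2% glucose.
    """

    # growth-rate composition
    lam0: float = 0.24            # basal, substrate-limited component
    lam_max_gain: float = 0.24    # sensor-driven gain at saturating glucose
    K_sens: float = 6.5           # half-saturation of sensing, mM
    lam_influx_gain: float = 0.23 # influx-fed component at saturating influx
    j_half: float = 1.0           # influx normalisation half-point

    # reserve bookkeeping
    R0: float = 6.8               # initial reserve (flux * h)
    y: float = 1.0                # biomass yield per influx unit
    demand_sens_amp: float = 6.0  # sensor drive amplifies consumption
    phi_r_scale: float = 0.6      # reserve fraction sustaining full growth
    g_r_gate: float = 0.4         # reserve fraction below which T lengthens
    g_cap: float = 200.0          # starvation cycle-time multiplier cap
    g_exp_base: float = 0.66      # starvation T-lengthening, sensor-independent
    g_exp_sens: float = 1.6       # extra lengthening under sensor drive
    K_g_sens: float = 0.06        # half-saturation of that coupling, 1/h
    famine_r: float = 0.1         # reserve fraction below which no cycle completes

    # division machinery
    influx_speedup: float = 0.8   # cycle-time shortening per unit normalised influx
    T_min: float = 1.2
    T_max: float = 6.0
    v_half: float = 3.51
    width: float = 0.6
    n: float = 2.2                # budding division ratio (daughter share 1/n)
    T_cap: float = 20.0

    # transporter expression
    vmax_per_dox: float = 0.0085   # Vmax per ng/ml doxycycline
    dox_sat: float = 4000.0        # ramp saturates here
    wt_vmax: float = 4.0
    wt_Km: float = 3.0

    # noise and observation
    sigma_lam: float = 0.04
    sigma_T: float = 0.07
    sigma_n: float = 0.04
    v0: float = math.log(40.0)    # founder log-size (maltose operating point)
    v0_jitter: float = 0.10
    frame_interval_h: float = 1.0 / 6.0
    measurement_cv: float = 0.05
    arrest_growth_h: float = 8.0  # growth persistence after division arrest


def influx(glucose_mM: float, Vmax: float, Km_mM: float = 10.0) -> float:
    """Michaelis-Menten glucose uptake ``J = Vmax * S / (Km + S)``."""
    if glucose_mM < 0 or Vmax < 0 or Km_mM <= 0:
        raise InvalidParameterError("influx needs S >= 0, Vmax >= 0, Km > 0")
    return Vmax * glucose_mM / (Km_mM + glucose_mM)


def _vmax(cond: Condition, p: PhysiologyParams) -> float:
    if cond.genotype == "WT":
        return p.wt_vmax
    if cond.genotype.startswith("transporterless"):
        return 0.0
    # single-HXT under the TET promoter: saturating linear dox ramp
    return p.vmax_per_dox * min(cond.dox_ng_ml, p.dox_sat)


def _transporter_km(cond: Condition, p: PhysiologyParams) -> float:
    return p.wt_Km if cond.genotype == "WT" else cond.Km_mM


def biomass_rate(cond: Condition, p: PhysiologyParams) -> float:
    """Sensor-gated specific growth-rate component, 1/h.

    ``lam = lam0 + lam_max_gain * S / (K_sens + S)`` with sensors,
    ``lam0`` without: strictly increasing in external glucose only when
    the Snf3/Rgt2 sensors are present.  (The influx-fed component is
    added separately by :func:`condition_rates`.)
    """
    S = cond.glucose_mM
    gain = p.lam_max_gain * S / (p.K_sens + S) if cond.sensors else 0.0
    return p.lam0 + gain


def reserve_dynamics(R: float, J: float, lam: float, V: float, dt: float,
                     y: float = 1.0) -> float:
    """One Euler step of the reserve pool: ``R + (J - y*lam*V)*dt``, floored at 0.

    Consumption is proportional to instantaneous biomass production, so
    a higher growth rate at equal influx depletes the pool faster.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    return max(0.0, R + (J - y * lam * V) * dt)


def cycle_time_modifier(R: float, R0: float, *, gate: float = 0.4,
                        cap: float = 200.0, exponent: float = 1.0) -> float:
    """Starvation multiplier g >= 1 on the cycle time.

    g = 1 while the reserve fraction is above ``gate``; below it the
    division cycle lengthens gradually, ``g = (gate / frac) **
    exponent`` (continuous at the gate), saturating at ``cap`` as the
    pool empties — which drives the effective cycle time past any
    arrest threshold.
    """
    if not 0 <= R <= R0 or R0 <= 0:
        raise InvalidParameterError("need 0 <= R <= R0 with R0 > 0")
    frac = R / R0
    if frac >= gate or exponent == 0:
        return 1.0
    return min(cap, (gate / max(frac, 1e-9)) ** exponent)


@dataclass(frozen=True)
class ConditionRates:
    """Resolved physiological rates for one condition."""

    j: float            # specific glucose influx
    j_norm: float       # j / (j + j_half), in [0, 1)
    lam_sens: float     # sensor-driven growth component
    lam_pot: float      # potential growth rate at full substrate
    demand: float       # reserve consumption rate
    h_influx: float     # cycle-time speed-up factor (<= 1)


def condition_rates(cond: Condition, p: PhysiologyParams) -> ConditionRates:
    j = influx(cond.glucose_mM, _vmax(cond, p), _transporter_km(cond, p))
    j_norm = j / (j + p.j_half)
    lam_sens = biomass_rate(cond, p) - p.lam0
    lam_pot = lam_sens + p.lam0 + p.lam_influx_gain * j_norm
    demand = p.y * lam_pot * (1.0 + p.demand_sens_amp * lam_sens)
    h_influx = 1.0 / (1.0 + p.influx_speedup * j_norm)
    return ConditionRates(j, j_norm, lam_sens, lam_pot, demand, h_influx)


def expected_regime(cond: Condition, p: PhysiologyParams,
                    lam_sens_arrest_split: float = 0.05) -> str:
    """Analytic ground-truth regime label for a condition.

    Steady state requires influx to cover the reserve consumption; in a
    deficit the outcome is set by whether sensor-driven growth persists
    once the pool empties: strong sensor drive keeps volume growing
    (large-cell, type II arrest), otherwise growth collapses while
    division limps on and cells shrink (small-cell, type I arrest).
    """
    r = condition_rates(cond, p)
    if r.j >= r.demand:
        return "STEADY"
    return "TYPE_II" if r.lam_sens >= lam_sens_arrest_split else "TYPE_I"


def _reserve_timecourse(rates: ConditionRates, p: PhysiologyParams,
                        duration_h: float, dt: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (t, R, phi, g) grids shared by every cell of a run.

    The reserve is bookkept per unit cell volume, so the pool is a
    property of the condition, not of colony size.
    """
    t = np.arange(0.0, duration_h + dt, dt)
    R = np.empty_like(t)
    R[0] = p.R0
    for i in range(1, len(t)):
        R[i] = min(p.R0, reserve_dynamics(R[i - 1], rates.j, rates.demand,
                                          1.0, dt, y=1.0))
    frac = R / p.R0
    phi = np.minimum(
        1.0, rates.j / max(rates.demand, 1e-12) + (frac / p.phi_r_scale) ** 2
    )
    # starvation lengthens the division cycle mostly when sensor-driven
    # biomass demand persists; unsensed cells divide at near-normal pace
    # on dwindling reserves instead (and shrink).
    coupling = rates.lam_sens / (rates.lam_sens + p.K_g_sens)
    p_eff = p.g_exp_base + p.g_exp_sens * coupling
    g = np.array([
        cycle_time_modifier(Ri, p.R0, gate=p.g_r_gate, cap=p.g_cap,
                            exponent=p_eff)
        for Ri in R
    ])
    return t, R, phi, g


def _simulate_condition_colony(
    cond: Condition,
    p: PhysiologyParams,
    seed: int,
    duration_h: float,
    max_cells: int,
    v0: float,
) -> pd.DataFrame:
    """Event table for one colony under the condition's physiology."""
    rates = condition_rates(cond, p)
    tgrid, R, phi, g = _reserve_timecourse(rates, p, duration_h)
    base_T = CycleTimeFunction(p.T_min, p.T_max, p.v_half, p.width)
    # once the reserve falls below the famine floor no division can
    # complete; cycles that would finish beyond that point arrest instead.
    famine_idx = np.nonzero(R / p.R0 < p.famine_r)[0]
    t_famine = float(tgrid[famine_idx[0]]) if len(famine_idx) else math.inf

    def interp(arr: np.ndarray, t: float) -> float:
        return float(np.interp(t, tgrid, arr))

    def lam_t(t: float) -> float:
        return rates.lam_sens + (p.lam0 + p.lam_influx_gain * rates.j_norm) \
            * interp(phi, t)

    def mech(v: float, t: float, lam: float) -> float:
        T = float(base_T(v)) * rates.h_influx * interp(g, t)
        if t + T > t_famine:
            return max(T, p.T_cap * 10.0)  # sentinel: survives noise, arrests
        return T

    params = GrowthParams(lam=rates.lam_pot, n=p.n, sigma_lam=p.sigma_lam,
                          sigma_T=p.sigma_T, sigma_n=p.sigma_n)
    config = SimulationConfig(seed=seed, t_max=duration_h, max_cells=max_cells,
                              T_cap=p.T_cap, v0=v0)
    return simulate_population(config, params, mech, n_founders=1, lam_t=lam_t)


def _frames_for_colony(events: pd.DataFrame, p: PhysiologyParams,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-frame size observations (10-min grid) from an event table."""
    dt = p.frame_interval_h
    t_end_obs = float(events["t_end_h"].max())
    n_frames = int(math.floor(t_end_obs / dt + 1e-9)) + 1
    grid = np.arange(n_frames) * dt

    times, ids, parents, sizes = [], [], [], []
    for row in events.itertuples(index=False):
        lo = int(math.ceil(row.t_start_h / dt - 1e-9))
        if row.outcome == "DIVIDED":
            hi = int(math.ceil(row.t_end_h / dt - 1e-9)) - 1  # next cycle covers t_end
        else:
            hi = int(math.floor(row.t_end_h / dt + 1e-9))
        if hi < lo:
            continue
        tt = grid[lo : hi + 1]
        age = tt - row.t_start_h
        if row.outcome == "ARRESTED":
            age = np.minimum(age, p.arrest_growth_h)  # growth persistence cap
        v = row.v_start + row.lam * age
        times.append(tt)
        ids.append(np.full(len(tt), row.cell_id, dtype=int))
        parents.append(np.full(len(tt), row.parent_id, dtype=int))
        sizes.append(np.exp(v))
    if not times:
        return pd.DataFrame(columns=["time_h", "cell_id", "parent_id", "size_fL"])
    df = pd.DataFrame(
        {
            "time_h": np.concatenate(times),
            "cell_id": np.concatenate(ids),
            "parent_id": np.concatenate(parents),
            "size_fL": np.concatenate(sizes),
        }
    )
    noise = np.exp(p.measurement_cv * rng.standard_normal(len(df)))
    df["size_fL"] = df["size_fL"] * noise
    return df.sort_values(["time_h", "cell_id"]).reset_index(drop=True)


def generate_tracking_table(
    cond: Condition,
    p: PhysiologyParams | None = None,
    seed: int = 0,
    duration_h: float = 30.0,
    n_positions: int = 3,
    max_cells_per_colony: int = 400,
    return_events: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full imaging run for one condition.

    Each position holds 1-3 colonies, each founded by a single cell;
    frames are emitted every 10 minutes with 5% multiplicative
    measurement noise.  A colony's observation ends at ``duration_h``
    or when it reaches ``max_cells_per_colony`` (the trap fills).
    Returns the tracking table (``TRACKING_COLUMNS``), plus the
    companion event table when ``return_events``.
    """
    if duration_h <= 0:
        raise InvalidParameterError("duration_h must be > 0")
    if p is None:
        p = PhysiologyParams()
    ss = np.random.SeedSequence(entropy=seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    frames_all, events_all = [], []
    cell_offset = 0
    for pos in range(n_positions):
        n_colonies = int(master.integers(1, 4))
        for col in range(n_colonies):
            sub = ss.spawn(1)[0]
            rng = np.random.default_rng(sub)
            colony_seed = int(rng.integers(0, 2**31 - 1))
            v0 = p.v0 + p.v0_jitter * rng.standard_normal()
            events = _simulate_condition_colony(
                cond, p, colony_seed, duration_h, max_cells_per_colony, v0
            )
            frames = _frames_for_colony(events, p, rng)
            for df in (frames, events):
                df["cell_id"] = df["cell_id"] + cell_offset
                df.loc[df["parent_id"] >= 0, "parent_id"] += cell_offset
            frames["position"] = pos
            frames["colony"] = col
            events["position"] = pos
            events["colony"] = col
            cell_offset += int(events["cell_id"].max()) - cell_offset + 1
            frames_all.append(frames)
            events_all.append(events)
    table = pd.concat(frames_all, ignore_index=True)[TRACKING_COLUMNS]
    if return_events:
        return table, pd.concat(events_all, ignore_index=True)
    return table
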