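"""Tests for the glucose-physiology synthetic-data generator."""

import math

import numpy as np
import pandas as pd
import pytest

from sizecontrol import (
    Condition,
    PhysiologyParams,
    biomass_rate,
    cycle_time_modifier,
    expected_regime,
    generate_tracking_table,
    influx,
    reserve_dynamics,
)
from sizecontrol.models import InvalidParameterError
from sizecontrol.physiology import TRACKING_COLUMNS, glucose_pct_to_mM
from sizecontrol.quantify import classify_arrest_table, colony_growth_curve, \
    division_rate


@pytest.fixture(scope="module")
def params():
    return PhysiologyParams()


class TestInflux:
    def test_zero_substrate(self):
        assert influx(0.0, 5.0) == 0.0

    def test_half_saturation(self):
        assert influx(10.0, 5.0, Km_mM=10.0) == pytest.approx(2.5)

    def test_one_percent_glucose(self):
        # 1% w/v = 55.5 mM; at Km = 10 mM uptake runs at 84.7% of Vmax
        s = glucose_pct_to_mM(1.0)
        assert s == pytest.approx(55.5, abs=0.1)
        assert influx(s, 1.0, Km_mM=10.0) == pytest.approx(0.847, abs=2e-3)


class TestBiomassRate:
    def test_sensorless_flat_in_glucose(self, params):
        vals = {biomass_rate(Condition("transporterless_sensorless", g), params)
                for g in (0.0, 0.01, 0.1, 2.0)}
        assert vals == {params.lam0}

    def test_zero_glucose_is_basal(self, params):
        assert biomass_rate(Condition("WT", 0.0), params) == params.lam0

    def test_monotone_with_sensors(self, params, rng):
        pairs = np.sort(rng.uniform(0.0, 2.0, size=(100, 2)), axis=1)
        for lo, hi in pairs:
            if hi - lo < 1e-9:
                continue
            assert biomass_rate(Condition("WT", lo), params) < biomass_rate(
                Condition("WT", hi), params
            )


class TestReserve:
    def test_balanced_flux_holds_reserve(self):
        R = 3.0
        for _ in range(50):
            R = reserve_dynamics(R, J=0.5, lam=0.25, V=2.0, dt=0.1)
        assert R == pytest.approx(3.0)

    def test_linear_depletion_time(self):
        R0, lam, V = 4.0, 0.2, 1.0
        R, t, dt = R0, 0.0, 0.01
        while R > 0:
            R = reserve_dynamics(R, J=0.0, lam=lam, V=V, dt=dt)
            t += dt
        assert t == pytest.approx(R0 / (lam * V), abs=0.05)

    def test_doubling_lam_halves_depletion(self):
        def t_empty(lam):
            R, t = 2.0, 0.0
            while R > 0:
                R = reserve_dynamics(R, 0.0, lam, 1.0, 0.005)
                t += 0.005
            return t

        assert t_empty(0.4) == pytest.approx(t_empty(0.2) / 2, rel=0.02)

    def test_modifier_bounds_and_monotonicity(self):
        assert cycle_time_modifier(5.0, 5.0) == 1.0
        grid = np.linspace(0, 5.0, 100)
        g = [cycle_time_modifier(R, 5.0) for R in grid]
        assert np.all(np.diff(g) <= 0)  # g falls as the reserve refills
        assert cycle_time_modifier(0.0, 5.0) >= 20.0 / 6.0  # forces T past T_cap


class TestTrackingTable:
    def test_schema_and_determinism(self, params):
        cond = Condition("WT", 0.1)
        a = generate_tracking_table(cond, params, seed=5, duration_h=12,
                                    n_positions=2, max_cells_per_colony=200)
        b = generate_tracking_table(cond, params, seed=5, duration_h=12,
                                    n_positions=2, max_cells_per_colony=200)
        assert list(a.columns) == TRACKING_COLUMNS
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_frames_on_ten_minute_grid(self, params):
        tab = generate_tracking_table(Condition("WT", 0.1), params, seed=2,
                                      duration_h=8, n_positions=1,
                                      max_cells_per_colony=100)
        frac = (tab["time_h"] * 6) % 1
        assert np.allclose(np.minimum(frac, 1 - frac), 0.0, atol=1e-9)

    def test_single_founder_per_colony(self, params):
        tab = generate_tracking_table(Condition("WT", 2.0), params, seed=3,
                                      duration_h=6, n_positions=3,
                                      max_cells_per_colony=100)
        first = tab[tab["time_h"] == 0.0]
        per_colony = first.groupby(["position", "colony"])["cell_id"].nunique()
        assert (per_colony == 1).all()

    def test_invalid_condition_rejected(self):
        with pytest.raises(InvalidParameterError):
            Condition("petite", 0.1)
        with pytest.raises(InvalidParameterError):
            Condition("WT", -0.1)


@pytest.mark.parametrize(
    "cond, expected",
    [
        (Condition("WT", 2.0), "STEADY"),
        (Condition("transporterless", 0.01), "TYPE_I"),
        (Condition("transporterless", 2.0), "TYPE_II"),
        (Condition("transporterless_sensorless", 2.0), "TYPE_I"),
    ],
)
def test_end_to_end_regimes(cond, expected, params):
    """The generator's regimes survive blind re-quantification."""
    assert expected_regime(cond, params) == expected
    tab = generate_tracking_table(cond, params, seed=11, duration_h=34,
                                  n_positions=2, max_cells_per_colony=1200)
    call, _ = classify_arrest_table(tab)
    assert call == expected


def test_initial_division_rate_independent_of_external_glucose(params):
    """Without influx, early divisions run near 0.3/h at any glucose level."""
    rates = {}
    for g in (0.0, 0.01, 0.1, 2.0):
        tab = generate_tracking_table(Condition("transporterless", g), params,
                                      seed=4, duration_h=8, n_positions=4,
                                      max_cells_per_colony=300)
        counts = colony_growth_curve(tab).groupby("time_h", as_index=False)[
            "n_cells"].sum()
        rates[g], _ = division_rate(counts, window=(0.0, 6.0))
    vals = np.array(list(rates.values()))
    assert np.all(vals > 0.2) and np.all(vals < 0.45)
    assert vals.mean() == pytest.approx(0.3, abs=0.06)
    assert vals.max() / vals.min() < 1.5


def test_zero_influx_transient_lasts_about_25_hours(params):
    """Reserve-fed division persists ~25 h before famine arrest."""
    tab, events = generate_tracking_table(
        Condition("transporterless", 0.0), params, seed=6, duration_h=30,
        n_positions=2, max_cells_per_colony=1000, return_events=True,
    )
    last_division = events.loc[events.outcome == "DIVIDED", "t_end_h"].max()
    assert 20.0 < last_division < 29.0


def test_dox_threshold_separates_steady_from_arrest(params):
    """Influx titration has a steady-state threshold: a dox level below
    which the 0.1%-glucose culture arrests large, above which it is steady."""
    low = generate_tracking_table(Condition("single_HXT", 0.1, dox_ng_ml=60),
                                  params, seed=8, duration_h=34,
                                  n_positions=2, max_cells_per_colony=1200)
    high = generate_tracking_table(Condition("single_HXT", 0.1, dox_ng_ml=1000),
                                   params, seed=8, duration_h=34,
                                   n_positions=2, max_cells_per_colony=1200)
    call_low, _ = classify_arrest_table(low)
    call_high, _ = classify_arrest_table(high)
    assert call_low == "TYPE_II"
    assert call_high == "STEADY"
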