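"""Unit and property tests for the discrete-generation size-control model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizecontrol import (
    CheckpointParams,
    CycleTimeFunction,
    GrowthParams,
    Regime,
    checkpoint_cycle_time,
    classify_regime,
    cycle_time,
    epsilon,
    find_fixed_point,
    log_size_update,
    non_exponential_update,
    phase_diagram,
    stability_at,
)
from sizecontrol.models import InvalidParameterError


@pytest.mark.parametrize(
    "v, lam, T, n, expected",
    [
        (0.0, math.log(2) / 3, 3.0, 2.0, 0.0),  # balanced: lam*T = log n
        (1.0, 0.35, 3.0, 2.0, 1.0 + 1.05 - math.log(2)),
        (2.0, 0.2, 2.0, 3.0, 2.0 + 0.4 - math.log(3)),
    ],
)
def test_log_size_update_examples(v, lam, T, n, expected):
    assert log_size_update(v, lam, T, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "lam, T, n, expected",
    [
        (math.log(2) / 4, 4.0, 2.0, 0.0),
        (0.3, 4.0, 2.0, 1.2 - math.log(2)),
        (0.1, 4.0, 2.0, 0.4 - math.log(2)),
    ],
)
def test_epsilon_examples(lam, T, n, expected):
    assert epsilon(lam, T, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [
    dict(v=0, lam=-0.1, T=2, n=2),
    dict(v=0, lam=0.2, T=0, n=2),
    dict(v=0, lam=0.2, T=2, n=1.0),
])
def test_invalid_cycle_parameters_rejected(bad):
    with pytest.raises(InvalidParameterError):
        log_size_update(**bad)


@given(
    v=st.floats(-5, 10),
    lam=st.floats(0.01, 2.0),
    T=st.floats(0.1, 30.0),
    n=st.floats(1.01, 5.0),
)
@settings(max_examples=200, derandomize=True)
def test_update_epsilon_identity(v, lam, T, n):
    """The per-cycle increment of the map is exactly the imbalance term."""
    assert log_size_update(v, lam, T, n) - v == pytest.approx(
        epsilon(lam, T, n), abs=1e-12
    )


class TestCycleTimeFunction:
    def test_limits_and_midpoint(self, gradual_f):
        assert cycle_time(-50.0, gradual_f) == pytest.approx(4.0, abs=1e-9)
        assert cycle_time(50.0, gradual_f) == pytest.approx(2.0, abs=1e-9)
        assert cycle_time(0.0, gradual_f) == pytest.approx(3.0, abs=1e-12)

    def test_monotone_and_bounded(self, gradual_f, rng):
        pairs = np.sort(rng.uniform(-10, 10, size=(1000, 2)), axis=1)
        t1, t2 = gradual_f(pairs[:, 0]), gradual_f(pairs[:, 1])
        assert np.all(t1 >= t2)
        for arr in (t1, t2):
            assert np.all(arr >= 2.0) and np.all(arr <= 4.0)

    def test_invalid_construction(self):
        with pytest.raises(InvalidParameterError):
            CycleTimeFunction(T_min=0.0, T_max=4.0)
        with pytest.raises(InvalidParameterError):
            CycleTimeFunction(T_min=4.0, T_max=2.0)


class TestFixedPoint:
    def test_exists_and_matches_grid_scan(self, homeostatic_params, gradual_f):
        v_star = find_fixed_point(homeostatic_params, gradual_f)
        assert v_star is not None
        assert abs(0.2 * gradual_f(v_star) - math.log(2)) < 1e-8
        # independent dense-grid oracle
        grid = np.linspace(-10, 10, 200001)
        resid = 0.2 * gradual_f(grid) - math.log(2)
        v_grid = grid[np.argmin(np.abs(resid))]
        assert v_star == pytest.approx(v_grid, abs=1e-4)

    @pytest.mark.parametrize("lam", [0.1, 0.4])
    def test_absent_outside_band(self, lam, gradual_f):
        assert find_fixed_point(GrowthParams(lam=lam), gradual_f) is None

    def test_stability_constant_T_is_marginal(self):
        f = CycleTimeFunction(T_min=3.0, T_max=3.0)  # T' = 0: random walk
        params = GrowthParams(lam=math.log(2) / 3.0)
        stable, m = stability_at(0.0, params, f)
        assert m == pytest.approx(1.0, abs=1e-9)
        assert not stable

    def test_multiplier_matches_finite_difference_of_map(
        self, homeostatic_params, gradual_f
    ):
        v_star = find_fixed_point(homeostatic_params, gradual_f)
        _, m = stability_at(v_star, homeostatic_params, gradual_f)
        h = 1e-5

        def step(v):
            return log_size_update(v, 0.2, gradual_f(v), 2.0)

        m_fd = (step(v_star + h) - step(v_star - h)) / (2 * h)
        assert m == pytest.approx(m_fd, abs=1e-4)

    def test_not_a_fixed_point_rejected(self, homeostatic_params, gradual_f):
        with pytest.raises(InvalidParameterError):
            stability_at(5.0, homeostatic_params, gradual_f)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "lam, expected",
        [(0.1, Regime.TYPE_I), (0.4, Regime.TYPE_II), (0.2, Regime.HOMEOSTATIC)],
    )
    def test_examples(self, lam, expected, gradual_f):
        res = classify_regime(GrowthParams(lam=lam), gradual_f)
        assert res.regime is expected
        assert (res.fixed_point is not None) == (expected is Regime.HOMEOSTATIC)

    def test_homeostatic_attaches_stability(self, homeostatic_params, gradual_f):
        res = classify_regime(homeostatic_params, gradual_f)
        assert res.stable is True
        assert abs(res.multiplier) < 1


class TestCheckpoint:
    def test_already_past_threshold(self):
        cp = CheckpointParams(v_crit=1.0, T_G1_min=0.5, T_budded=1.5)
        assert checkpoint_cycle_time(1.2, cp, lam=0.3) == pytest.approx(2.0)

    def test_growth_to_threshold(self):
        cp = CheckpointParams(v_crit=1.0, T_G1_min=0.5, T_budded=1.0)
        # needs (1.0 - 0.7)/0.3 = 1.0 h of G1 growth
        assert checkpoint_cycle_time(0.7, cp, lam=0.3) == pytest.approx(2.0)

    def test_timer_caps_the_wait(self):
        cp = CheckpointParams(v_crit=0.0, T_G1_min=0.5, T_budded=1.0, tau_max=5.0)
        assert checkpoint_cycle_time(-10.0, cp, lam=0.3) == pytest.approx(6.0)


class TestPhaseDiagram:
    def make_grid(self):
        lams = np.linspace(0.05, 0.5, 12)
        fams = [CycleTimeFunction(a, b, 0.0, 1.0)
                for a, b in [(1.5, 3.0), (2.0, 4.0), (2.5, 6.0), (1.0, 8.0)]]
        return lams, fams

    def test_boundaries_and_monotonicity_in_lam(self):
        lams, fams = self.make_grid()
        df = phase_diagram(lams, fams, n=2.0)
        order = {"TYPE_I": 0, "HOMEOSTATIC": 1, "TYPE_II": 2}
        for (tmin, tmax), sub in df.groupby(["T_min", "T_max"]):
            sub = sub.sort_values("lam")
            codes = sub["regime"].map(order).to_numpy()
            assert np.all(np.diff(codes) >= 0)  # never skips backward
            assert set(np.diff(codes)) <= {0, 1}  # no TYPE_I -> TYPE_II jump
            # boundary: classification is TYPE_I exactly when lam*T_max < log 2
            expect_I = sub["lam"] * tmax < math.log(2)
            assert ((sub["regime"] == "TYPE_I") == expect_I).all()

    def test_fixed_point_increases_with_lam(self):
        f = CycleTimeFunction(2.0, 4.0, 0.0, 1.0)
        lams = np.linspace(math.log(2) / 4 + 0.01, math.log(2) / 2 - 0.01, 20)
        v_stars = [find_fixed_point(GrowthParams(lam=l), f) for l in lams]
        assert all(v is not None for v in v_stars)
        assert np.all(np.diff(v_stars) > 0)


class TestNonExponentialGrowth:
    def test_linear_growth_fixed_point(self):
        a, T = 5.0, 2.0
        v_star = math.log(a * T)  # V + a*T = 2V  =>  V* = a*T
        out = non_exponential_update(v_star, "linear", T, 2.0, a=a)
        assert out == pytest.approx(v_star, abs=1e-12)

    def test_exponential_reduces_to_log_size_update(self):
        out = non_exponential_update(1.3, "exponential", 3.0, 2.0, lam=0.35)
        assert out == pytest.approx(log_size_update(1.3, 0.35, 3.0, 2.0))

    @pytest.mark.parametrize("factor", [0.1, 10.0])
    def test_linear_map_converges_without_size_dependent_T(self, factor):
        """Sub-exponential growth alone stabilises size, even with constant T."""
        a, T = 5.0, 2.0
        v_star = math.log(a * T)
        v = math.log(factor * a * T)
        for k in range(60):
            v = non_exponential_update(v, "linear", T, 2.0, a=a)
            if abs(v - v_star) < 1e-6:
                break
        assert abs(v - v_star) < 1e-6

    def test_unknown_law_rejected(self):
        with pytest.raises(InvalidParameterError):
            non_exponential_update(0.0, "cubic", 1.0, 2.0)


def test_balanced_growth_is_a_fixed_line(rng):
    """When lam*T = log n exactly, iteration leaves any size unchanged."""
    for _ in range(20):
        n = rng.uniform(1.5, 4.0)
        T = rng.uniform(1.0, 6.0)
        lam = math.log(n) / T
        v = v0 = rng.uniform(-2, 6)
        for _ in range(100):
            v = log_size_update(v, lam, T, n)
        assert abs(v - v0) < 1e-9
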