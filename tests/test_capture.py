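"""Capture engine: kernel, daily escape products, the Monte-Carlo driver and
its invariants (brute-force equality, common-random-number monotonicity,
cohort-size insensitivity)."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from trapsurvey import (AttractionKernel, DispersalParams, SimConfig,
                        TrapLayout, capture_prob_at_distance, daily_escape,
                        run_simulation)
from trapsurvey.capture import _iteration_log_escape


class TestKernel:
    @pytest.mark.parametrize("d,lam_inv,expected", [
        (0.0, 10.0, 1.0),
        (10.0, 10.0, math.exp(-1)),
        (20.0, 10.0, math.exp(-2)),
        (40.0, 20.0, math.exp(-2)),
    ])
    def test_exponential_decay(self, d, lam_inv, expected):
        assert capture_prob_at_distance(d, AttractionKernel(lam_inv)) == \
            pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self):
        kernel = AttractionKernel(25.0)
        d = np.linspace(0, 500, 100)
        p = capture_prob_at_distance(d, kernel)
        assert np.all(np.diff(p) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            capture_prob_at_distance(-1.0, AttractionKernel(10.0))

    def test_nonpositive_attraction_rejected(self):
        with pytest.raises(ValueError):
            AttractionKernel(0.0)


class TestDailyEscape:
    def test_empty_layout_escapes_certainly(self):
        empty = TrapLayout(np.empty(0), np.empty(0), np.empty(0))
        assert daily_escape((123.0, -456.0), empty) == 1.0

    def test_insect_at_trap_never_escapes(self, single_trap_layout):
        assert daily_escape((15.0, 0.0), single_trap_layout) == 0.0

    def test_two_trap_product(self):
        """Traps at 10 m and 20 m with 1/λ = 10 m: (1−e⁻¹)(1−e⁻²)."""
        layout = TrapLayout(np.array([10.0, 20.0]), np.zeros(2),
                            np.array([10.0, 10.0]))
        expected = (1 - math.exp(-1)) * (1 - math.exp(-2))
        assert daily_escape((0.0, 0.0), layout) == pytest.approx(expected, rel=1e-12)


class TestEngineOracle:
    def test_brute_force_equality(self):
        """3 traps, 2 insects, 2 days with hand-fixed positions: the engine's
        per-day cumulative mean escape equals the hand-computed product-mean
        to 1e-12."""
        layout = TrapLayout(np.array([0.0, 50.0, -30.0]),
                            np.array([0.0, 20.0, -40.0]),
                            np.array([10.0, 20.0, 15.0]))
        positions = np.array([[[5.0, 5.0], [100.0, -50.0]],
                              [[20.0, 0.0], [-25.0, -35.0]]])  # (day, insect, 2)
        escape = np.ones((2, 2))
        for day in range(2):
            for ins in range(2):
                for j in range(3):
                    d = math.hypot(positions[day, ins, 0] - layout.x[j],
                                   positions[day, ins, 1] - layout.y[j])
                    escape[day, ins] *= 1 - math.exp(-d / layout.lam_inv[j])
        expected = np.cumprod(escape, axis=0).mean(axis=1)

        tree = cKDTree(layout.coords)
        daily_log = _iteration_log_escape(positions, layout, tree,
                                          46.0 * layout.lam_inv.max())
        got = np.exp(np.cumsum(daily_log, axis=0)).mean(axis=1)
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)

    def test_single_trap_single_day_closed_form(self, single_trap_layout):
        """One insect, one day, D = 0, epicenter pinned at the origin: the
        cumulative capture probability is the kernel itself, exp(−d/(1/λ))."""
        disp = DispersalParams(D=0.0, epicenter_side_m=1e-15)
        cfg = SimConfig(iterations=3, duration_days=1, n_insects=1, seed=0)
        result = run_simulation(single_trap_layout, disp, cfg)
        assert result.p_capture_final == pytest.approx(math.exp(-1.5), abs=1e-9)


class TestRunSimulation:
    def test_zero_traps_zero_capture(self, leek_disp, fast_cfg):
        empty = TrapLayout(np.empty(0), np.empty(0), np.empty(0))
        result = run_simulation(empty, leek_disp, fast_cfg)
        assert result.p_capture_final == 0.0
        assert np.all(result.p_escape_by_day == 1.0)

    def test_deterministic_given_seed(self, single_trap_layout, leek_disp, fast_cfg):
        a = run_simulation(single_trap_layout, leek_disp, fast_cfg)
        b = run_simulation(single_trap_layout, leek_disp, fast_cfg)
        np.testing.assert_array_equal(a.p_escape_by_day, b.p_escape_by_day)
        np.testing.assert_array_equal(a.ci95_by_day, b.ci95_by_day)

    def test_result_invariants(self, leek_layout, leek_disp, fast_cfg):
        result = run_simulation(leek_layout, leek_disp, fast_cfg)
        p = result.p_capture_by_day
        assert np.all((0 <= p) & (p <= 1))
        assert np.all(np.diff(p) >= 0), "cumulative capture must not decrease"
        np.testing.assert_allclose(result.p_escape_by_day + p, 1.0, rtol=0, atol=1e-15)

    def test_monotone_in_trap_count_under_crn(self, leek_disp, fast_cfg):
        """With identical seeds, adding traps cannot lower p(capture)."""
        few = TrapLayout(np.array([50.0]), np.array([0.0]), np.array([20.0]))
        more = TrapLayout(np.array([50.0, -80.0, 0.0]),
                          np.array([0.0, 40.0, -60.0]),
                          np.array([20.0, 20.0, 20.0]))
        p_few = run_simulation(few, leek_disp, fast_cfg).p_capture_by_day
        p_more = run_simulation(more, leek_disp, fast_cfg).p_capture_by_day
        assert np.all(p_more >= p_few)

    def test_monotone_in_attractiveness_under_crn(self, leek_disp, fast_cfg):
        weak = TrapLayout(np.array([50.0]), np.array([0.0]), np.array([10.0]))
        strong = TrapLayout(np.array([50.0]), np.array([0.0]), np.array([30.0]))
        p_weak = run_simulation(weak, leek_disp, fast_cfg).p_capture_by_day
        p_strong = run_simulation(strong, leek_disp, fast_cfg).p_capture_by_day
        assert np.all(p_strong >= p_weak)

    def test_monotone_in_duration(self, single_trap_layout, leek_disp):
        """Extending the survey only adds capture opportunities; the shared
        seed makes the shorter run a prefix of the longer one."""
        short = run_simulation(single_trap_layout, leek_disp,
                               SimConfig(iterations=20, duration_days=5,
                                         n_insects=10, seed=3))
        long = run_simulation(single_trap_layout, leek_disp,
                              SimConfig(iterations=20, duration_days=15,
                                        n_insects=10, seed=3))
        assert long.p_capture_final >= long.p_capture_by_day[4] >= 0
        assert np.all(np.diff(long.p_capture_by_day) >= 0)
        assert short.p_capture_final <= long.p_capture_final + 1e-12

    def test_cohort_size_insensitivity(self, leek_disp):
        """Expected p(capture) does not depend on the outbreak size; only the
        Monte-Carlo variance does."""
        layout = TrapLayout(np.array([100.0, -150.0]), np.array([0.0, 80.0]),
                            np.array([20.0, 20.0]))
        small = run_simulation(layout, leek_disp,
                               SimConfig(iterations=300, duration_days=10,
                                         n_insects=5, seed=21))
        large = run_simulation(layout, leek_disp,
                               SimConfig(iterations=300, duration_days=10,
                                         n_insects=50, seed=22))
        joint = math.hypot(small.ci95_halfwidth, large.ci95_halfwidth)
        assert abs(small.p_capture_final - large.p_capture_final) <= joint

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(iterations=0)
        with pytest.raises(ValueError):
            SimConfig(duration_days=0)
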