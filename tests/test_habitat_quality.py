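import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habiquant import (
    Grid,
    HQConfig,
    ThreatSpec,
    change_map,
    classify_quality,
    decay_factor,
    degradation,
    quality,
    threat_presence,
)
from habiquant.raster_io import LandUseLegend, LegendEntry

from conftest import brute_force_degradation


class TestThreatPresence:
    def test_no_sources_all_zero(self, mini_legend, mini_threats):
        lu = Grid(np.ones((4, 4)))
        p = threat_presence(lu, mini_threats[0], mini_legend)
        assert not p.valid_values().any()

    def test_direct_membership(self, mini_legend, mini_threats):
        lu = Grid(np.array([[2.0, 1.0], [1.0, 2.0]]))
        p = threat_presence(lu, mini_threats[0], mini_legend)
        np.testing.assert_array_equal(p.values, [[1.0, 0.0], [0.0, 1.0]])

    def test_count_matches_class_area(self, mini_legend, mini_threats):
        rng = np.random.default_rng(4)
        lu = Grid(rng.integers(1, 4, size=(10, 10)).astype(float))
        p = threat_presence(lu, mini_threats[0], mini_legend)
        assert p.valid_values().sum() == (lu.values == 2).sum()

    def test_nodata_propagates(self, mini_legend, mini_threats):
        lu = Grid(np.array([[2.0, -9999.0]]))
        p = threat_presence(lu, mini_threats[0], mini_legend)
        assert not p.valid_mask[0, 1]


class TestDecayFactor:
    def test_zero_distance_gives_one(self, mini_threats):
        for t in mini_threats:
            assert decay_factor(0.0, t) == pytest.approx(1.0)

    def test_linear_hits_zero_at_max_distance(self):
        t = ThreatSpec("t", frozenset({1}), d_rmax=3.5, weight=1.0, decay="linear")
        assert decay_factor(3.5, t) == pytest.approx(0.0)

    def test_exponential_at_max_distance_is_exp_minus_299(self):
        t = ThreatSpec("t", frozenset({1}), d_rmax=5.0, weight=1.0, decay="exponential")
        assert decay_factor(5.0, t) == pytest.approx(math.exp(-2.99), rel=1e-12)
        assert decay_factor(5.0, t) == pytest.approx(0.05029, abs=5e-6)

    def test_truncated_beyond_max_distance(self, mini_threats):
        for t in mini_threats:
            assert decay_factor(t.d_rmax * 1.01, t) == 0.0

    def test_negative_distance_rejected(self, mini_threats):
        with pytest.raises(ValueError):
            decay_factor(-0.1, mini_threats[0])

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 10.0), st.floats(0.1, 10.0))
    def test_decay_in_unit_interval(self, d, dmax):
        for kind in ("linear", "exponential"):
            t = ThreatSpec("t", frozenset({1}), d_rmax=dmax, weight=1.0, decay=kind)
            assert 0.0 <= decay_factor(d, t) <= 1.0


class TestDegradation:
    def test_no_sources_zero_everywhere(self, mini_legend, mini_threats):
        lu = Grid(np.ones((5, 5)))
        d = degradation(lu, mini_threats, mini_legend)
        np.testing.assert_allclose(d.valid_values(), 0.0)

    def test_single_source_closed_form(self):
        # one central urban cell radiating over a uniform habitat with S = 0.5
        legend = LandUseLegend(
            {
                1: LegendEntry(1, "habitat", 0.9, {"urban": 0.5}),
                2: LegendEntry(2, "urban", 0.0, {"urban": 0.5}),
            }
        )
        threat = ThreatSpec("urban", frozenset({2}), d_rmax=2.0, weight=1.0, decay="exponential")
        lu = Grid(np.ones((3, 3)))
        lu.values[1, 1] = 2.0
        d = degradation(lu, [threat], legend)
        assert d.values[0, 1] == pytest.approx(math.exp(-2.99 / 2.0) * 0.5, rel=1e-12)
        assert d.values[0, 0] == pytest.approx(math.exp(-2.99 * math.sqrt(2) / 2.0) * 0.5, rel=1e-12)
        # the source cell itself is exposed at distance zero
        assert d.values[1, 1] == pytest.approx(0.5, rel=1e-12)

    def test_weight_rescaling_invariance(self, mini_legend, mini_threats):
        rng = np.random.default_rng(8)
        lu = Grid(rng.integers(1, 4, size=(12, 12)).astype(float))
        d1 = degradation(lu, mini_threats, mini_legend)
        scaled = [
            ThreatSpec(t.name, t.source_codes, t.d_rmax, t.weight * 7.3, t.decay)
            for t in mini_threats
        ]
        d2 = degradation(lu, scaled, mini_legend)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_quadruple_loop(self, mini_legend, mini_threats, seed):
        rng = np.random.default_rng(seed)
        shape = (12, 14)
        vals = rng.integers(1, 4, size=shape).astype(float)
        vals[rng.random(shape) < 0.08] = -9999.0
        lu = Grid(vals, cell_size=0.8)
        fast = degradation(lu, mini_threats, mini_legend)
        slow = brute_force_degradation(lu, mini_threats, mini_legend)
        mask = lu.valid_mask
        assert np.max(np.abs(fast.values[mask] - slow.values[mask])) < 1e-12

    def test_shrinking_reach_never_increases_d(self, mini_legend, mini_threats):
        rng = np.random.default_rng(9)
        lu = Grid(rng.integers(1, 4, size=(15, 15)).astype(float))
        d_full = degradation(lu, mini_threats, mini_legend)
        shrunk = [
            ThreatSpec(t.name, t.source_codes, t.d_rmax * 0.5, t.weight, t.decay)
            for t in mini_threats
        ]
        d_half = degradation(lu, shrunk, mini_legend)
        mask = lu.valid_mask
        assert np.all(d_half.values[mask] <= d_full.values[mask] + 1e-12)

    def test_all_zero_weights_rejected(self, mini_legend):
        t = ThreatSpec("urban", frozenset({2}), 2.0, 0.0, "linear")
        with pytest.raises(ValueError, match="weights"):
            degradation(Grid(np.ones((3, 3))), [t], mini_legend)


class TestQuality:
    def test_zero_suitability_absorbs(self, mini_legend):
        lu = Grid(np.full((3, 3), 2.0))  # urban, H = 0
        d = Grid(np.full((3, 3), 0.7))
        q = quality(lu, d, mini_legend)
        np.testing.assert_allclose(q.valid_values(), 0.0)

    def test_no_degradation_returns_suitability(self, mini_legend):
        lu = Grid(np.ones((4, 4)))
        d = Grid(np.zeros((4, 4)))
        q = quality(lu, d, mini_legend)
        np.testing.assert_allclose(q.valid_values(), 0.9)

    def test_half_saturation_halves_quality(self):
        legend = LandUseLegend({1: LegendEntry(1, "forest", 0.99, {"t": 0.5})})
        cfg = HQConfig(z=2.5, k=0.5)
        lu = Grid(np.ones((2, 2)))
        d = Grid(np.full((2, 2), cfg.k))
        q = quality(lu, d, legend, cfg)
        np.testing.assert_allclose(q.valid_values(), 0.495)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 5.0),
        st.floats(0.0, 5.0),
        st.floats(0.5, 4.0),
        st.floats(0.1, 2.0),
    )
    def test_monotone_nonincreasing_in_degradation(self, d1, d2, z, k):
        legend = LandUseLegend({1: LegendEntry(1, "h", 0.8, {"t": 0.5})})
        cfg = HQConfig(z=z, k=k)
        lo, hi = sorted((d1, d2))
        lu = Grid(np.ones((1, 1)))
        q_lo = quality(lu, Grid(np.full((1, 1), lo)), legend, cfg).values[0, 0]
        q_hi = quality(lu, Grid(np.full((1, 1), hi)), legend, cfg).values[0, 0]
        assert q_hi <= q_lo + 1e-12

    def test_zero_sensitivity_everywhere_gives_q_equals_h(self, mini_threats):
        legend = LandUseLegend(
            {
                1: LegendEntry(1, "forest", 0.9, {"urban": 0.0, "farm": 0.0}),
                2: LegendEntry(2, "urban", 0.0, {"urban": 0.0, "farm": 0.0}),
                3: LegendEntry(3, "farm", 0.4, {"urban": 0.0, "farm": 0.0}),
            }
        )
        rng = np.random.default_rng(10)
        lu = Grid(rng.integers(1, 4, size=(10, 10)).astype(float))
        d = degradation(lu, mini_threats, legend)
        q = quality(lu, d, legend)
        expected = np.vectorize(legend.suitability)(lu.values.astype(int))
        np.testing.assert_allclose(q.values, expected, atol=1e-12)


class TestClassification:
    def test_bin_lookup_medium(self):
        q = Grid(np.full((2, 2), 0.534))
        grades, table = classify_quality(q)
        assert np.all(grades.values == 3)
        assert table.percents["medium"] == pytest.approx(100.0)

    def test_left_closed_boundaries(self):
        q = Grid(np.array([[0.2, 0.4], [0.6, 0.8]]))
        grades, _ = classify_quality(q)
        np.testing.assert_array_equal(grades.values, [[2, 3], [4, 5]])

    def test_one_is_highest(self):
        q = Grid(np.array([[1.0, 0.9]]))
        grades, table = classify_quality(q)
        assert np.all(grades.values == 5)
        assert table.percents["highest"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(12)
        q = Grid(rng.random((20, 20)))
        _, table = classify_quality(q)
        assert table.percents.sum() == pytest.approx(100.0, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_quality(Grid(np.array([[1.2]])))


class TestChangeMap:
    def test_identical_surfaces_unchanged(self):
        q = Grid(np.random.default_rng(1).random((5, 5)))
        _, table = change_map(q, q)
        assert table["unchanged"] == pytest.approx(100.0)

    def test_uniform_improvement(self):
        a = Grid(np.full((4, 4), 0.4))
        b = Grid(np.full((4, 4), 0.6))
        cmap, table = change_map(a, b, eps=0.01)
        assert table["improved"] == pytest.approx(100.0)
        assert np.all(cmap.values == 1.0)

    def test_half_up_half_down(self):
        a = Grid(np.full((2, 4), 0.5))
        delta = np.array([[0.1] * 4, [-0.1] * 4])
        b = Grid(a.values + delta)
        _, table = change_map(a, b, eps=0.01)
        assert table["improved"] == pytest.approx(50.0)
        assert table["degraded"] == pytest.approx(50.0)
        assert table["unchanged"] == pytest.approx(0.0)

    def test_partition_sums_to_100(self):
        rng = np.random.default_rng(13)
        a, b = Grid(rng.random((10, 10))), Grid(rng.random((10, 10)))
        _, table = change_map(a, b)
        assert table.sum() == pytest.approx(100.0, abs=1e-9)
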