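"""Smoothing, penalized change-point segmentation, uniform regridding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from era_lfp import (
    detect_change_points,
    generate_piecewise_linear,
    interpolate_to_uniform,
    moving_average_smooth,
)


class TestMovingAverage:
    def test_window_one_is_identity(self, rng):
        y = rng.standard_normal(50)
        assert np.array_equal(moving_average_smooth(y, 1), y)

    def test_constant_series_unchanged(self):
        y = np.full(20, 3.7)
        assert np.allclose(moving_average_smooth(y, 5), y)

    def test_linear_series_invariant_with_truncated_ends(self):
        # interior means of a linear ramp equal the ramp; symmetric
        # truncation leaves the first/last samples untouched
        y = np.arange(5, dtype=float) + 1
        assert np.allclose(moving_average_smooth(y, 3), y)

    def test_matches_naive_windowed_mean(self, rng):
        y = rng.standard_normal(31)
        w = 7
        out = moving_average_smooth(y, w)
        for i in range(31):
            h = min(w // 2, i, 30 - i)
            assert np.isclose(out[i], y[i - h:i + h + 1].mean())

    def test_even_or_bad_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average_smooth(np.zeros(10), 4)
        with pytest.raises(ValueError, match="odd"):
            moving_average_smooth(np.zeros(10), 0)
        with pytest.raises(ValueError, match="exceeds"):
            moving_average_smooth(np.zeros(3), 5)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=60),
           st.sampled_from([1, 3, 5]))
    def test_contraction_on_range(self, values, window):
        y = np.array(values)
        out = moving_average_smooth(y, window)
        assert np.all(out >= y.min() - 1e-9)
        assert np.all(out <= y.max() + 1e-9)


class TestChangePoints:
    def test_straight_line_keeps_endpoints_only(self):
        y = 2.0 * np.arange(100) - 5.0
        cp = detect_change_points(y, penalty=0.01)
        assert cp.n_interior == 0
        assert np.allclose(cp.values, [y[0], y[-1]])

    def test_single_knot_recovered_exactly(self):
        rec = generate_piecewise_linear([0.0, 1.0, 2.0], [0.0, 1.0, -0.5], rate=50.0)
        cp = detect_change_points(rec.samples[0], rate=50.0, penalty=1e-3)
        assert np.allclose(cp.times, [0.0, 1.0, 2.0])
        assert np.allclose(cp.values, [0.0, 1.0, -0.5])

    @pytest.mark.parametrize("penalty", [1e-4, 1e-3, 1e-2])
    def test_17_knot_fixture_recovered(self, rng, penalty):
        kt = np.arange(17.0)
        kv = rng.standard_normal(17)
        rec = generate_piecewise_linear(kt, kv, rate=100.0)
        cp = detect_change_points(rec.samples[0], rate=100.0, penalty=penalty)
        assert cp.times.size == 17
        assert np.allclose(np.sort(cp.times), kt, atol=1e-12)
        resid = rec.samples[0] - cp.interpolate(rec.times())
        assert np.abs(resid).max() < 1e-10

    def test_compression_on_noisy_trend_fixture(self, rng):
        # thousands of raw samples reduce to tens of knots
        kt = np.linspace(0, 10, 12)
        kv = rng.standard_normal(12) * 5
        rec = generate_piecewise_linear(kt, kv, rate=400.0, noise_sd=0.3, seed=1)
        cp = detect_change_points(rec.samples[0], rate=400.0, penalty=5.0)
        assert rec.n_samples > 3000
        assert 2 <= cp.times.size <= 80

    def test_penalty_monotone_and_nested(self, rng):
        y = np.cumsum(rng.standard_normal(1500)) * 0.1
        penalties = [1e-3, 1e-2, 0.1, 1.0, 10.0]
        sets = [set(detect_change_points(y, penalty=p).times.tolist())
                for p in penalties]
        counts = [len(s) for s in sets]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for small, big in zip(sets, sets[1:]):
            assert big <= small  # larger penalty keeps a subset of knots

    def test_max_cps_cap(self, rng):
        y = rng.standard_normal(500)
        cp = detect_change_points(y, penalty=1e-6, max_cps=10)
        assert cp.n_interior <= 10

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            detect_change_points(np.array([1.0]), penalty=1.0)
        with pytest.raises(ValueError, match="penalty"):
            detect_change_points(np.zeros(10), penalty=0.0)


class TestInterpolateToUniform:
    def test_knots_on_grid_reproduced_exactly(self):
        from era_lfp import ChangePointSet
        cp = ChangePointSet(channel_id="c", times=np.arange(5.0),
                            values=np.array([0.0, 1.0, 0.0, 1.0, 0.0]),
                            source_length=5)
        out = interpolate_to_uniform([cp], target_points=5)
        assert np.allclose(out.samples[0], [0, 1, 0, 1, 0])

    def test_linear_signal_any_grid(self):
        y = np.linspace(-2, 7, 200)
        cp = detect_change_points(y, rate=10.0, penalty=0.01)
        out = interpolate_to_uniform([cp], target_points=37)
        expected = np.linspace(-2, 7, 37)
        assert np.allclose(out.samples[0], expected, atol=1e-10)

    def test_disjoint_knot_times_share_grid(self, rng):
        y1 = rng.standard_normal(300)
        y2 = rng.standard_normal(300)
        cps = [detect_change_points(y, rate=50.0, penalty=0.5, channel_id=f"c{i}")
               for i, y in enumerate((y1, y2))]
        out = interpolate_to_uniform(cps, target_points=64)
        assert out.samples.shape == (2, 64)

    def test_mismatched_spans_rejected(self, rng):
        c1 = detect_change_points(rng.standard_normal(100), rate=10.0, penalty=0.5)
        c2 = detect_change_points(rng.standard_normal(50), rate=10.0, penalty=0.5,
                                  channel_id="short")
        with pytest.raises(ValueError, match="short"):
            interpolate_to_uniform([c1, c2], target_points=20)


def test_roundtrip_piecewise_linear_exact(rng):
    """Segmenter + regridding reproduces noise-free piecewise-linear input."""
    kt = np.sort(rng.uniform(0, 20, 15))
    kt[0], kt[-1] = 0.0, 20.0
    kt = np.round(kt * 50) / 50  # knots on the sampling grid
    kt = np.unique(kt)
    kv = rng.standard_normal(kt.size)
    rec = generate_piecewise_linear(kt, kv, rate=50.0)
    cp = detect_change_points(rec.samples[0], rate=50.0, penalty=1e-3)
    out = interpolate_to_uniform([cp], target_points=777)
    truth = np.interp(out.times(), kt, kv)
    assert np.abs(out.samples[0] - truth).max() < 1e-10
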