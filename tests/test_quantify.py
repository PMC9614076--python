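"""The movement statistic E[n] and its aggregation/exclusion contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uwbmotion.phantom import Scenario, simulate_radar
from uwbmotion.preprocess import ClutterModel, subtract_background
from uwbmotion.quantify import (ExclusionIntervals, ThresholdProfile,
                                aggregate_per_second, apply_exclusions,
                                estimate_threshold, quantify_movement)


def naive_movement(frames, t, l_signal):
    """Triple-loop transliteration of the movement equation (oracle)."""
    n_frames, _ = frames.shape
    e = np.zeros(n_frames)
    for n in range(1, n_frames):
        total = 0.0
        for k in range(l_signal + 1):
            if frames[n, k] > t[k]:
                total += abs(frames[n, k] - frames[n - 1, k])
        e[n] = total
    return e


def profile(t):
    return ThresholdProfile(t=np.asarray(t, dtype=float))


class TestQuantifyMovement:
    def test_hand_worked_two_frame_example(self, series_factory):
        # only bin 1 passes the gate AND differs between the frames;
        # bin 3 passes the gate but its difference is zero
        series = series_factory([[0, 5, 0, 2], [0, 8, 0, 2]])
        out = quantify_movement(series, profile([1, 1, 1, 1]), l_signal=3)
        assert out.e[0] == 0.0
        assert out.e[1] == 3.0

    def test_hand_worked_example_with_degenerate_attribution(self,
                                                             series_factory):
        series = series_factory([[0, 5, 0, 2], [0, 8, 0, 2]])
        out = quantify_movement(series, profile([1, 1, 1, 1]), l_signal=0)
        assert np.all(out.e == 0.0)

    def test_constant_frames_give_zero(self, series_factory):
        series = series_factory(np.tile([3.0, 4.0, 5.0], (50, 1)))
        out = quantify_movement(series, profile([0, 0, 0]), l_signal=2)
        assert np.all(out.e == 0.0)

    def test_matches_naive_oracle_bit_exactly(self, series_factory, rng):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            k = int(rng.integers(1, 33))
            frames = rng.normal(size=(n, k))
            t = np.abs(rng.normal(size=k))
            l_signal = int(rng.integers(0, k))
            fast = quantify_movement(series_factory(frames), profile(t),
                                     l_signal).e
            slow = naive_movement(frames, t, l_signal)
            assert np.array_equal(fast, slow)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), bump=st.floats(0.01, 2.0))
    def test_raising_threshold_never_increases_e(self, seed, bump):
        from conftest import make_series
        rng = np.random.default_rng(seed)
        frames = rng.normal(size=(30, 8))
        t = np.abs(rng.normal(size=8))
        lo = quantify_movement(make_series(frames), profile(t), 7).e
        t2 = t.copy()
        t2[int(rng.integers(0, 8))] += bump
        hi = quantify_movement(make_series(frames), profile(t2), 7).e
        assert np.all(hi <= lo)

    def test_growing_attribution_range_never_decreases_e(self, series_factory,
                                                         rng):
        frames = rng.normal(size=(40, 16))
        t = np.abs(rng.normal(size=16))
        prev = np.zeros(40)
        for l_signal in range(16):
            e = quantify_movement(series_factory(frames), profile(t), l_signal).e
            assert np.all(e >= prev)
            prev = e

    def test_shape_mismatch_rejected(self, series_factory):
        series = series_factory(np.ones((10, 4)))
        with pytest.raises(ValueError, match="threshold length"):
            quantify_movement(series, profile([1, 1]), 1)
        with pytest.raises(ValueError, match="l_signal"):
            quantify_movement(series, profile([1, 1, 1, 1]), 4)

    def test_static_phantom_scene_is_exactly_zero(self):
        sc = Scenario(duration_s=20.0, noise_sigma=0.0,
                      respiration_amplitude=0.0)
        series = subtract_background(simulate_radar(sc, "left"),
                                     ClutterModel("mean"))
        threshold = estimate_threshold(series, calibration_window_s=(0, 5))
        out = quantify_movement(series, threshold, sc.body_center_bin)
        assert np.all(out.e == 0.0)


class TestEstimateThreshold:
    @pytest.mark.parametrize("method", ["quantile", "mean_plus_c_sigma"])
    def test_all_zero_window_gives_zero_threshold(self, series_factory, method):
        series = series_factory(np.zeros((100, 6)))
        t = estimate_threshold(series, method=method).t
        assert np.all(t == 0.0)

    def test_constant_amplitude_mean_plus_sigma_equals_amplitude(
            self, series_factory):
        series = series_factory(np.full((100, 6), 2.5))
        t = estimate_threshold(series, method="mean_plus_c_sigma").t
        assert np.allclose(t, 2.5)

    def test_quantile_matches_empirical_quantile_of_same_draw(
            self, series_factory, rng):
        frames = rng.normal(size=(5000, 4))
        t = estimate_threshold(series_factory(frames), method="quantile",
                               params={"q": 0.95}).t
        expected = np.quantile(np.abs(frames), 0.95, axis=0)
        assert np.array_equal(t, expected)
        # half-normal 0.95 quantile for sigma=1 is ~1.96
        assert np.allclose(t, 1.96, atol=0.1)

    def test_empty_calibration_window_rejected(self, series_factory):
        series = series_factory(np.ones((100, 4)))
        with pytest.raises(ValueError, match="empty calibration"):
            estimate_threshold(series, calibration_window_s=(50.0, 51.0))


class TestAggregation:
    def test_constant_frames_average(self, series_factory):
        series = series_factory(np.zeros((20, 2)))
        from uwbmotion.quantify import MovementSeries
        ms = MovementSeries(e=np.full(20, 2.0), frame_rate=20.0)
        assert np.array_equal(aggregate_per_second(ms).per_second, [2.0])

    def test_trailing_partial_second_dropped(self):
        from uwbmotion.quantify import MovementSeries
        ms = MovementSeries(e=np.ones(39), frame_rate=20.0)
        assert aggregate_per_second(ms).per_second.shape == (1,)

    def test_alternating_values_average(self):
        from uwbmotion.quantify import MovementSeries
        e = np.tile([0.0, 4.0], 10)
        ms = MovementSeries(e=e, frame_rate=20.0)
        assert np.array_equal(aggregate_per_second(ms).per_second, [2.0])


class TestExclusions:
    def make(self, n_sec=10):
        from uwbmotion.quantify import MovementSeries
        ms = MovementSeries(e=np.ones(n_sec * 20), frame_rate=20.0)
        return aggregate_per_second(ms)

    def test_empty_interval_list_is_identity(self):
        ms = self.make()
        out = apply_exclusions(ms, ExclusionIntervals([]))
        assert np.array_equal(out.per_second, ms.per_second)

    def test_full_session_exclusion_blanks_everything(self):
        out = apply_exclusions(self.make(), ExclusionIntervals([(0, 100)]))
        assert np.all(np.isnan(out.per_second))

    def test_any_overlap_excludes_the_second(self):
        out = apply_exclusions(self.make(), ExclusionIntervals([(1.5, 2.5)]))
        assert np.isnan(out.per_second[1]) and np.isnan(out.per_second[2])
        assert np.isfinite(out.per_second[[0, 3]]).all()

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="must be <"):
            ExclusionIntervals([(5.0, 2.0)])
        with pytest.raises(ValueError, match="malformed"):
            ExclusionIntervals([("a",)])

    def test_overlapping_intervals_merged(self):
        iv = ExclusionIntervals([(3, 5), (1, 4)])
        assert iv.intervals == ((1.0, 5.0),)
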