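"""Kinematic metrics: worked arithmetic, sign conventions, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reachtrack as rt
from reachtrack.segment import Segment


def _series_from_x(camera, x, y=None):
    x = np.asarray(x, float)
    y = np.full_like(x, 240.0) if y is None else np.asarray(y, float)
    return rt.CentroidSeries.from_positions(camera, x, y, 24.0)


class TestInstantaneousSpeed:
    def test_two_pixel_step(self, camera):
        series = _series_from_x(camera, [100.0, 102.0])
        v = rt.instantaneous_speed(series, 0)
        # 2 px * (183/752 mm/px) * 30 fps
        assert v == pytest.approx(2 * camera.mm_per_px * camera.fps, rel=1e-12)
        assert v == pytest.approx(14.60, abs=0.01)

    def test_stationary_is_zero(self, camera):
        series = _series_from_x(camera, [100.0, 100.0])
        assert rt.instantaneous_speed(series, 0) == 0.0

    def test_invalid_frame_undefined(self, camera):
        series = _series_from_x(camera, [100.0, 102.0, 104.0])
        series.valid[1] = False
        v = rt.instantaneous_speeds(series)
        assert np.isnan(v[0]) and np.isnan(v[1])


class TestSegmentSpeed:
    def test_constant_velocity_exact(self, camera):
        series = _series_from_x(camera, 100.0 + 3.0 * np.arange(10))
        seg = Segment("travel", "large1", 0, 0, 10, "rightward")
        v = rt.segment_mean_speed(seg, series)
        assert v == pytest.approx(3.0 * camera.mm_per_px * camera.fps,
                                  rel=1e-12)

    def test_invalid_frame_excluded_from_mean(self, camera):
        series = _series_from_x(camera, 100.0 + 3.0 * np.arange(10))
        series.valid[4] = False
        seg = Segment("travel", "large1", 0, 0, 10, "rightward")
        v = rt.segment_mean_speed(seg, series)
        assert v == pytest.approx(3.0 * camera.mm_per_px * camera.fps,
                                  rel=1e-12)

    def test_endpoint_segment_rejected(self, camera):
        series = _series_from_x(camera, np.arange(10.0))
        seg = Segment("endpoint", "large1", 0, 0, 10, "rightward")
        with pytest.raises(ValueError):
            rt.segment_mean_speed(seg, series)

    def test_generator_segment_matches_ground_truth(self, noiseless_sim):
        seg = noiseless_sim.travel_segments[0]
        v = rt.segment_mean_speed(seg, noiseless_sim.series)
        assert v == pytest.approx(noiseless_sim.travel_mean_speed_mm_s[0],
                                  rel=0.01)


class TestAcceleration:
    def test_constant_velocity_is_zero(self, camera):
        series = _series_from_x(camera, 100.0 + 3.0 * np.arange(10))
        seg = Segment("travel", "large1", 0, 0, 10, "rightward")
        assert rt.segment_mean_acceleration(seg, series) == \
            pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_speed_steps(self, camera):
        # consecutive speeds 10, 20, 30 mm/s at 30 fps -> samples (300, 300)
        step = 1.0 / camera.mm_per_px / camera.fps  # px per frame per mm/s
        x = np.cumsum([0.0, 10 * step, 20 * step, 30 * step]) + 100.0
        series = _series_from_x(camera, x)
        seg = Segment("travel", "large1", 0, 0, 4, "rightward")
        assert rt.segment_mean_acceleration(seg, series) == \
            pytest.approx(300.0, rel=1e-9)

    def test_too_short_segment_is_undefined(self, camera):
        series = _series_from_x(camera, np.arange(3.0))
        seg = Segment("travel", "large1", 0, 0, 3, "rightward")
        assert np.isnan(rt.segment_mean_acceleration(seg, series))

    def test_matches_finite_difference_oracle_on_generator(self, protocol,
                                                           camera):
        """Implementation agrees with a brute-force finite-difference
        oracle applied to the generator's positions."""
        p = rt.SubjectParams(speed_mult=1.5, accel_jitter_sd=40.0)
        sim = rt.simulate_trial(p, protocol, camera, seed=3)
        seg = sim.travel_segments[7]
        x = sim.series.x[seg.start:seg.end]
        y = sim.series.y[seg.start:seg.end]
        v = np.hypot(np.diff(x), np.diff(y)) * camera.mm_per_px * camera.fps
        oracle = np.mean(np.abs(np.diff(v))) * camera.fps
        got = rt.segment_mean_acceleration(seg, sim.series)
        assert got == pytest.approx(oracle, rel=0.02)


class TestSpeedError:
    @pytest.mark.parametrize("speed,expected", [
        (51.4, 100.0), (25.7, 0.0), (26.985, 5.0)])
    def test_anchor_values(self, speed, expected):
        assert rt.percent_speed_error(speed) == pytest.approx(expected,
                                                              abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=500.0),
           st.floats(min_value=0.01, max_value=500.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_zero_at_training(self, a, b):
        if a == b:
            assert rt.percent_speed_error(a) == rt.percent_speed_error(b)
        else:
            lo, hi = sorted([a, b])
            assert rt.percent_speed_error(lo) < rt.percent_speed_error(hi)
        assert rt.percent_speed_error(25.7) == 0.0


class TestCenterOffset:
    def _endpoint(self, camera, protocol, direction, reversal_offset_px):
        (lx, cy), (rx, _) = protocol.target_centers_px(camera)
        cx = rx if direction == "rightward" else lx
        d = 1.0 if direction == "rightward" else -1.0
        # approach, reverse at cx + d*reversal_offset_px, back off
        x = np.array([cx - d * 30, cx - d * 10,
                      cx + d * reversal_offset_px, cx - d * 10])
        series = _series_from_x(camera, x)
        seg = Segment("endpoint", "large1", 0, 1, 3, direction)
        return seg, series

    def test_reversal_at_center_is_zero(self, camera, protocol):
        seg, series = self._endpoint(camera, protocol, "rightward", 0.0)
        assert rt.center_offset(seg, series, protocol) == \
            pytest.approx(0.0, abs=1e-9)

    def test_rightward_overreach_positive(self, camera, protocol):
        seg, series = self._endpoint(camera, protocol, "rightward", 10.0)
        assert rt.center_offset(seg, series, protocol) == \
            pytest.approx(10 * camera.mm_per_px, rel=1e-9)
        assert rt.center_offset(seg, series, protocol) == \
            pytest.approx(2.434, abs=0.01)

    def test_leftward_underreach_negative(self, camera, protocol):
        seg, series = self._endpoint(camera, protocol, "leftward", -10.0)
        assert rt.center_offset(seg, series, protocol) == \
            pytest.approx(-10 * camera.mm_per_px, rel=1e-9)


class TestIPA:
    def test_four_of_five_inside_is_80(self, camera, protocol):
        x_lo, x_hi, y_lo, y_hi = protocol.roi_bounds("large1", camera)
        x = np.linspace(x_lo + 10, x_hi - 10, 5)
        y = np.array([240.0, 240.0, y_hi + 20.0, 240.0, 240.0])
        series = _series_from_x(camera, x, y)
        ipa = rt.intertarget_path_accuracy(np.arange(5), series, "large1",
                                           protocol)
        assert ipa == pytest.approx(80.0, abs=1e-12)

    def test_all_inside_is_100(self, noiseless_sim, noiseless_table):
        assert (noiseless_table["ipa_pct"] == 100.0).all()

    def test_boundary_counts_as_inside(self, camera, protocol):
        x_lo, x_hi, y_lo, y_hi = protocol.roi_bounds("small", camera)
        series = _series_from_x(camera, [x_lo, x_hi], [y_lo, y_hi])
        ipa = rt.intertarget_path_accuracy([0, 1], series, "small", protocol)
        assert ipa == 100.0

    def test_monotone_decrease_with_path_noise(self, protocol, camera):
        """Mean IPA over simulated subtasks decreases as lateral jitter
        grows (three noise levels)."""
        means = []
        for sd in (1.0, 4.0, 8.0):
            vals = []
            for seed in range(3):
                sim = rt.simulate_trial(
                    rt.SubjectParams(speed_mult=2.0, path_noise_sd=sd),
                    protocol, camera, seed=seed)
                recs, _ = rt.trial_metrics(sim.series, protocol)
                vals.extend(r.ipa for r in recs)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestSummaries:
    def test_six_records_per_trial(self, noiseless_table):
        assert len(noiseless_table) == 6
        assert list(noiseless_table["subtask"]) == list(
            rt.Protocol().subtask_order)

    def test_noiseless_round_trip(self, noiseless_table, protocol):
        assert np.allclose(noiseless_table["speed_mmps"],
                           protocol.training_speed_mm_s, rtol=1e-9)
        assert np.allclose(noiseless_table["speed_error_pct"], 0.0,
                           atol=1e-6)
        assert np.allclose(noiseless_table["center_offset_mm"], 0.0,
                           atol=1e-9)

    def test_hand_built_two_segment_mean(self, camera, protocol):
        """Toy series with two constant-speed travel segments: summary
        equals the hand-computed mean of the two segment speeds."""
        x = np.concatenate([100.0 + 2.0 * np.arange(10),
                            130.0 + 4.0 * np.arange(10)])
        series = _series_from_x(camera, x)
        segs = [Segment("travel", "large1", 0, 0, 10, "rightward"),
                Segment("travel", "large1", 1, 10, 20, "rightward")]
        recs = rt.summarize_trial(series, segs, protocol)
        rec = next(r for r in recs if r.subtask_id == "large1")
        v1 = 2.0 * camera.mm_per_px * camera.fps
        v2 = 4.0 * camera.mm_per_px * camera.fps
        assert rec.mean_speed == pytest.approx((v1 + v2) / 2, rel=1e-12)
        missing = [r for r in recs if r.subtask_id != "large1"]
        assert all(r.missing for r in missing)

    def test_scale_equivariance(self, camera, protocol):
        """Doubling all displacements doubles mean speed and acceleration."""
        rng = np.random.default_rng(0)
        steps = 3.0 + rng.normal(0, 0.3, 19)
        x1 = 100.0 + np.concatenate([[0.0], np.cumsum(steps)])
        x2 = 100.0 + np.concatenate([[0.0], np.cumsum(2 * steps)])
        seg = Segment("travel", "large1", 0, 0, 20, "rightward")
        s1 = _series_from_x(camera, x1)
        s2 = _series_from_x(camera, x2)
        assert rt.segment_mean_speed(seg, s2) == \
            pytest.approx(2 * rt.segment_mean_speed(seg, s1), rel=1e-12)
        assert rt.segment_mean_acceleration(seg, s2) == \
            pytest.approx(2 * rt.segment_mean_acceleration(seg, s1),
                          rel=1e-12)
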