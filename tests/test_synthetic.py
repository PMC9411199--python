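"""Synthetic-data generators: determinism, conservation, ground truth."""
import numpy as np
import pytest

from flyvnc.synthetic import (
    ArenaTrajectorySpec,
    ConnectiveMovieSpec,
    DegradationSeriesSpec,
    SensorTraceSpec,
    WaveSpec,
    generate_arena_trajectory,
    generate_connective_movie,
    generate_degradation_series,
    generate_sensor_traces,
)
from flyvnc.treadmill import sensors_to_velocities


class TestConnectiveMovie:
    def test_no_motion_gives_zero_fields_and_static_red(self):
        spec = ConnectiveMovieSpec(
            n_frames=5, motion_amplitude=0, nonrigid_amplitude=0, noise_sd=0, seed=1
        )
        red, _, truth = generate_connective_movie(spec)
        for f in truth.true_motion_fields:
            assert f.magnitude().max() == 0.0
        for t in range(1, 5):
            np.testing.assert_array_equal(red.data[t], red.data[0])

    def test_constant_traces_give_static_green(self):
        spec = ConnectiveMovieSpec(
            n_frames=5, motion_amplitude=0, nonrigid_amplitude=0, noise_sd=0,
            fluctuation_amplitude=0.0, wave=None, seed=2,
        )
        _, green, _ = generate_connective_movie(spec)
        for t in range(1, 5):
            np.testing.assert_array_equal(green.data[t], green.data[0])

    def test_deterministic_under_seed(self):
        spec = ConnectiveMovieSpec(n_frames=4, seed=7)
        r1, g1, t1 = generate_connective_movie(spec)
        r2, g2, t2 = generate_connective_movie(spec)
        np.testing.assert_array_equal(r1.data, r2.data)
        np.testing.assert_array_equal(g1.data, g2.data)
        np.testing.assert_array_equal(t1.roi_masks, t2.roi_masks)
        for f1, f2 in zip(t1.true_motion_fields, t2.true_motion_fields):
            np.testing.assert_array_equal(f1.dy, f2.dy)

    def test_intensity_conserved_without_motion_or_noise(self):
        spec = ConnectiveMovieSpec(
            n_frames=6, motion_amplitude=0, nonrigid_amplitude=0, noise_sd=0, seed=3
        )
        red, _, _ = generate_connective_movie(spec)
        totals = red.data.sum(axis=(1, 2))
        np.testing.assert_allclose(totals, totals[0], rtol=1e-12)

    def test_wave_peaks_strictly_increase_along_region_order(self):
        spec = ConnectiveMovieSpec(
            n_frames=160, wave=WaveSpec(inter_region_lag=0.5), seed=4,
            motion_amplitude=0, noise_sd=0,
        )
        _, _, truth = generate_connective_movie(spec)
        order = {r: i for i, r in enumerate(spec.wave.region_order)}
        by_region = {}
        for label, t_peak in truth.wave_peak_times.items():
            by_region.setdefault(truth.roi_regions[label], set()).add(t_peak)
        peaks = [by_region[r].pop() for r in spec.wave.region_order]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_roi_labels_unique_per_pixel_and_gain_positive(self):
        spec = ConnectiveMovieSpec(n_frames=2, illumination_slope=0.002, seed=5)
        _, _, truth = generate_connective_movie(spec)
        assert truth.illumination_gain.min() > 0
        assert set(np.unique(truth.roi_masks)) == set(range(0, spec.n_axons + 1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ConnectiveMovieSpec(n_frames=0)
        with pytest.raises(ValueError):
            ConnectiveMovieSpec(noise_sd=-1)


class TestSensorTraces:
    def test_all_zero_segments_fully_stationary(self):
        spec = SensorTraceSpec(duration=5.0, sensor_noise_sd=0.0, seed=1)
        traces, truth = generate_sensor_traces(spec)
        assert np.all(traces.values == 0)
        assert truth.stationary_intervals == [(0.0, 5.0)]

    def test_forward_rotation_round_trip(self):
        spec = SensorTraceSpec(
            duration=4.0, segments=[(1.0, 3.0, 0.5, 0.0, 0.0)], sensor_noise_sd=0.0
        )
        traces, _ = generate_sensor_traces(spec)
        vel = sensors_to_velocities(traces)
        mid = slice(int(1.5 * 400), int(2.5 * 400))
        np.testing.assert_allclose(vel.forward[mid], 0.5, atol=1e-12)
        np.testing.assert_allclose(vel.sideways[mid], 0.0, atol=1e-12)
        np.testing.assert_allclose(vel.turning[mid], 0.0, atol=1e-12)

    def test_sample_count(self):
        traces, _ = generate_sensor_traces(SensorTraceSpec(duration=10.0, rate=400.0))
        assert traces.n_samples == 4000

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            SensorTraceSpec(segments=[(0, 2, 1, 0, 0), (1, 3, 1, 0, 0)])

    def test_deterministic(self):
        spec = SensorTraceSpec(
            duration=2.0, segments=[(0.5, 1.0, 0.3, 0.1, 0.0)],
            sensor_noise_sd=0.05, seed=9,
        )
        t1, _ = generate_sensor_traces(spec)
        t2, _ = generate_sensor_traces(spec)
        np.testing.assert_array_equal(t1.values, t2.values)


class TestArenaTrajectory:
    def test_default_session_is_59_seconds(self):
        traj, _ = generate_arena_trajectory(ArenaTrajectorySpec(seed=0))
        assert traj.n_frames / traj.rate == pytest.approx(59.0)

    def test_instant_peak_distance_is_three_times_peak_speed(self):
        spec = ArenaTrajectorySpec(
            noise_sd=0.0, response_slope=1e5, recovery_fraction=0.0, seed=0
        )
        _, truth = generate_arena_trajectory(spec)
        for m in truth.true_metrics:
            assert m.backward_distance == pytest.approx(
                -3.0 * spec.backward_peak_speed, rel=0.01
            )

    def test_no_stimulation_means_no_metrics(self):
        traj, truth = generate_arena_trajectory(ArenaTrajectorySpec(n_stims=0, seed=0))
        assert truth.true_metrics == []
        assert traj.n_frames / traj.rate == pytest.approx(30.0)

    def test_deterministic(self):
        spec = ArenaTrajectorySpec(noise_sd=0.5, seed=11)
        t1, _ = generate_arena_trajectory(spec)
        t2, _ = generate_arena_trajectory(spec)
        np.testing.assert_array_equal(t1.centroid, t2.centroid)


class TestDegradationSeries:
    def test_static_series_when_all_rates_zero(self):
        spec = DegradationSeriesSpec(
            n_days=4, bleach_rate=0, amputation_decay_rate=0, jitter=0,
            noise_sd=0, n_flies_per_group=1, seed=1,
        )
        series_list, _ = generate_degradation_series(spec)
        for series in series_list:
            for d in range(1, 4):
                np.testing.assert_array_equal(series.images[d], series.images[0])

    def test_closed_form_decay_of_roi_mean(self):
        k = 0.3
        spec = DegradationSeriesSpec(
            n_days=8, bleach_rate=0.0, amputation_decay_rate=k, jitter=0,
            noise_sd=0, n_flies_per_group=1, seed=2,
        )
        series_list, truth = generate_degradation_series(spec)
        amputated = next(s for s in series_list if s.group == "amputated")
        roi = truth.roi_masks == 1  # designated decaying ROI
        day1 = amputated.images[0][roi].mean()
        for d_idx, day in enumerate(amputated.days):
            expected = day1 * (np.exp(-k * (day - 2)) if day >= 2 else 1.0)
            assert amputated.images[d_idx][roi].mean() == pytest.approx(expected, rel=1e-9)

    def test_jitter_recoverable_by_registration(self):
        from flyvnc.registration import register_translation

        spec = DegradationSeriesSpec(
            n_days=4, bleach_rate=0.0, amputation_decay_rate=0.0, jitter=2.5,
            noise_sd=0, n_flies_per_group=1, seed=3,
        )
        series_list, truth = generate_degradation_series(spec)
        series = series_list[0]
        jitter = truth.extras["jitter"][series.fly_id]
        for d in range(1, 4):
            dy, dx = register_translation(series.images[d], series.images[0])
            assert dy == pytest.approx(jitter[d, 0], abs=0.2)
            assert dx == pytest.approx(jitter[d, 1], abs=0.2)

    def test_deterministic(self):
        spec = DegradationSeriesSpec(n_days=3, n_flies_per_group=2, seed=5)
        s1, _ = generate_degradation_series(spec)
        s2, _ = generate_degradation_series(spec)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.images, b.images)

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            DegradationSeriesSpec(n_days=1)
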