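"""Wave statistics: normalization, Mann-Whitney tests, peak-time maps."""
import numpy as np
import pytest

from flyvnc.datatypes import FrameStack, SampledTrace
from flyvnc.waves import (
    NormalizationConstant,
    compute_normalization,
    connective_mean_trace,
    global_peak_time,
    mann_whitney_u,
    max_normalized_activity,
    nonmoving_mean_image,
    pixel_peak_time_map,
    roi_trace_normalize,
)


class TestConnectiveMeanTrace:
    def test_constant_stack(self):
        stack = FrameStack(np.full((5, 8, 8), 3.0))
        trace = connective_mean_trace(stack, np.ones((8, 8), dtype=bool))
        np.testing.assert_allclose(trace.values, 3.0)

    def test_two_pixel_mask(self):
        data = np.zeros((1, 2, 2))
        data[0, 0, 0], data[0, 0, 1] = 1.0, 3.0
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, :] = True
        trace = connective_mean_trace(FrameStack(data), mask)
        assert trace.values[0] == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            connective_mean_trace(
                FrameStack(np.ones((2, 4, 4))), np.zeros((4, 4), dtype=bool)
            )


class TestNormalization:
    def test_constant_trace(self):
        norm = compute_normalization([SampledTrace(np.full(100, 5.0), 16)])
        assert norm.value == 5.0

    def test_linear_interpolation_percentile(self):
        # 1..100: the 99th percentile interpolates to 99.01
        norm = compute_normalization([SampledTrace(np.arange(1.0, 101.0), 16)])
        assert norm.value == pytest.approx(99.01)

    def test_self_normalization_is_unity(self):
        rng = np.random.default_rng(0)
        trace = SampledTrace(rng.uniform(10, 50, 500), 16)
        norm = compute_normalization([trace])
        assert max_normalized_activity(trace, norm) == pytest.approx(1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        trace = SampledTrace(rng.uniform(1, 2, 300), 16)
        norm = NormalizationConstant(2.0)
        scaled = SampledTrace(3.0 * trace.values, 16)
        assert max_normalized_activity(scaled, norm) == pytest.approx(
            3.0 * max_normalized_activity(trace, norm)
        )


class TestMannWhitney:
    def test_one_sided_normal_cc_complete_separation_3v3(self):
        """z = (9 - 4.5 - 0.5)/sqrt(5.25) gives p = 0.0404."""
        from scipy.stats import norm

        a, b = [4.0, 5.0, 6.0], [1.0, 2.0, 3.0]
        p = mann_whitney_u(a, b, sides="one", method="normal_cc")
        oracle = float(norm.sf((9 - 4.5 - 0.5) / np.sqrt(5.25)))
        assert p == pytest.approx(oracle, abs=1e-6)
        assert p == pytest.approx(0.0404, abs=5e-4)

    def test_one_sided_exact_3v3(self):
        # only 1 of C(6,3) = 20 orderings is as extreme
        p = mann_whitney_u([4, 5, 6], [1, 2, 3], sides="one", method="exact")
        assert p == pytest.approx(1 / 20)

    def test_two_sided_exact_5v5(self):
        # 2 of C(10,5) = 252 orderings
        p = mann_whitney_u(
            [6, 7, 8, 9, 10], [1, 2, 3, 4, 5], sides="two", method="exact"
        )
        assert p == pytest.approx(2 / 252)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_normal_cc_tracks_exact_under_separation(self, n):
        a = list(range(n, 2 * n))
        b = list(range(n))
        p_exact = mann_whitney_u(a, b, sides="one", method="exact")
        p_normal = mann_whitney_u(a, b, sides="one", method="normal_cc")
        assert abs(p_exact - p_normal) < 0.02

    def test_all_tied_returns_one(self):
        with pytest.warns(UserWarning):
            assert mann_whitney_u([1, 1], [1, 1]) == 1.0


class TestRoiTraceNormalize:
    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(2)
        out = roi_trace_normalize(SampledTrace(rng.normal(size=200), 16))
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        out1 = roi_trace_normalize(SampledTrace(x, 16))
        out2 = roi_trace_normalize(SampledTrace(2.5 * x + 7.0, 16))
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)

    def test_impulse_peak_position_preserved(self):
        x = np.zeros(200)
        x[100] = 1.0
        out = roi_trace_normalize(SampledTrace(x, 16))
        assert int(np.argmax(out.values)) == 100

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            roi_trace_normalize(SampledTrace(np.ones(50), 16))


class TestGlobalPeakTime:
    def test_triangular_bump(self):
        rate = 16.0
        t = np.arange(400) / rate
        values = np.maximum(0, 1 - np.abs(t - 12.0))
        assert global_peak_time(SampledTrace(values, rate)) == pytest.approx(12.0)

    def test_tie_breaks_to_earliest(self):
        rate = 1.0
        values = np.zeros(12)
        values[5] = values[9] = 1.0
        assert global_peak_time(SampledTrace(values, rate)) == 5.0


class TestPixelPeakTimeMap:
    def test_uniform_flash_maps_to_zero(self):
        rate = 16.0
        T = 400
        t = np.arange(T) / rate
        flash = np.exp(-0.5 * ((t - 12.0) / 1.0) ** 2)
        stack = FrameStack(np.tile(flash[:, None, None], (1, 6, 6)), rate)
        peak_map = pixel_peak_time_map(stack, 12.0)
        np.testing.assert_allclose(peak_map, 0.0, atol=1.0 / rate)

    def test_time_translation_equivariance(self):
        rng = np.random.default_rng(4)
        rate = 16.0
        T = 500
        t = np.arange(T) / rate
        base = np.exp(-0.5 * ((t[:, None, None] - 14.0 - rng.uniform(0, 2, (1, 5, 5))) / 1.0) ** 2)
        stack = FrameStack(base, rate)
        k = 32  # shift by 2 s
        shifted = FrameStack(np.roll(base, k, axis=0), rate)
        m1 = pixel_peak_time_map(stack, 15.0)
        m2 = pixel_peak_time_map(shifted, 15.0 + k / rate)
        np.testing.assert_allclose(m1, m2, atol=1.0 / rate)

    def test_wave_region_order_recovered(self):
        """Traveling wave: per-ROI median peak times follow the true phase
        order (noise-free, lag of several frames)."""
        from scipy.stats import spearmanr

        from flyvnc.synthetic import ConnectiveMovieSpec, WaveSpec, generate_connective_movie

        spec = ConnectiveMovieSpec(
            n_frames=160, motion_amplitude=0, nonrigid_amplitude=0, noise_sd=0,
            fluctuation_amplitude=0.0,
            wave=WaveSpec(onset_time=3.0, inter_region_lag=0.5, amplitude=4.0),
            seed=6,
        )
        _, green, truth = generate_connective_movie(spec)
        trace = connective_mean_trace(green, truth.roi_masks > 0)
        t_peak = global_peak_time(trace)
        peak_map = pixel_peak_time_map(green, t_peak)
        labels = sorted(truth.wave_peak_times)
        recovered = [np.median(peak_map[truth.roi_masks == l]) for l in labels]
        true_phase = [truth.wave_peak_times[l] for l in labels]
        rho = spearmanr(true_phase, recovered).statistic
        assert rho >= 0.9
        # exact region order for >= 2-frame lags
        order_rec = np.argsort(recovered, kind="stable")
        order_true = np.argsort(true_phase, kind="stable")
        region_of = truth.roi_regions
        rec_regions = [region_of[labels[i]] for i in order_rec]
        true_regions = [region_of[labels[i]] for i in order_true]
        assert rec_regions == true_regions


class TestNonmovingMean:
    def test_all_frames_equals_temporal_mean(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1, (6, 4, 4))
        stack = FrameStack(data)
        out = nonmoving_mean_image(stack, np.ones(6, dtype=bool))
        np.testing.assert_allclose(out, data.mean(axis=0))

    def test_single_frame_mask(self):
        data = np.stack([np.full((3, 3), 1.0), np.full((3, 3), 9.0)])
        mask = np.array([True, False])
        np.testing.assert_allclose(
            nonmoving_mean_image(FrameStack(data), mask), 1.0
        )

    def test_no_stationary_frames_rejected(self):
        with pytest.raises(ValueError):
            nonmoving_mean_image(FrameStack(np.ones((3, 2, 2))), np.zeros(3, bool))
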