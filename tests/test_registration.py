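"""Motion-correction stage: COM alignment, optic flow, warping."""
import numpy as np
import pytest
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from flyvnc.datatypes import FrameStack, MotionField
from flyvnc.registration import (
    OpticFlowParams,
    _hs_flow_energy,
    _hs_iterate,
    center_of_mass_register,
    crop_center,
    estimate_motion_field,
    register_translation,
    warp_bilinear,
)


def smooth_image(seed=0, shape=(64, 96), scale=100.0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(scale, 30.0, shape), 3.0)


def subpixel_shift(img, dy, dx):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(img, np.stack([yy - dy, xx - dx]), order=1, mode="nearest")


class TestCenterOfMass:
    def test_single_frame_is_noop(self):
        stack = FrameStack(smooth_image()[None])
        out, offsets = center_of_mass_register(stack)
        assert np.array_equal(offsets, [[0, 0]])
        np.testing.assert_array_equal(out.data, stack.data)

    def test_recovers_integer_shift(self):
        ref = np.zeros((64, 96))
        ref[20:30, 40:55] = 100.0
        frame = np.roll(ref, (3, 5), axis=(0, 1))
        stack = FrameStack(np.stack([ref, frame]))
        out, offsets = center_of_mass_register(stack)
        # applied correction undoes the (3, 5) content shift
        assert tuple(offsets[1]) == (-3, -5)
        np.testing.assert_allclose(out.data[1], ref)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        data = np.stack(
            [subpixel_shift(smooth_image(5), *rng.uniform(-4, 4, 2)) for _ in range(4)]
        )
        once, _ = center_of_mass_register(FrameStack(data))
        twice, offsets2 = center_of_mass_register(once)
        assert np.all(np.abs(offsets2) <= 1)  # COM matched within a pixel

    def test_all_zero_frame_warns(self):
        data = np.stack([smooth_image(1), np.zeros((64, 96))])
        with pytest.warns(UserWarning):
            _, offsets = center_of_mass_register(FrameStack(data))
        assert tuple(offsets[1]) == (0, 0)


class TestCropCenter:
    def test_acquisition_to_connective_crop(self):
        stack = FrameStack(np.arange(480 * 736, dtype=float).reshape(1, 480, 736))
        out = crop_center(stack, 352, 576)
        assert out.shape == (1, 352, 576)
        # 64 and 80 pixel margins removed symmetrically
        np.testing.assert_array_equal(out.data[0], stack.data[0, 64:416, 80:656])

    def test_identity_when_target_equals_shape(self):
        stack = FrameStack(smooth_image()[None])
        out = crop_center(stack, 64, 96)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_odd_margin_removed_from_high_side(self):
        stack = FrameStack(np.arange(100, dtype=float).reshape(1, 10, 10))
        out = crop_center(stack, 7, 7)
        np.testing.assert_array_equal(out.data[0], stack.data[0, 1:8, 1:8])

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError):
            crop_center(FrameStack(np.zeros((1, 8, 8))), 9, 8)


class TestEstimateMotionField:
    def test_zero_motion_fixed_point(self):
        for seed in range(3):
            img = smooth_image(seed)
            field = estimate_motion_field(img, img)
            assert field.magnitude().mean() < 0.05

    def test_translation_matches_phase_correlation(self):
        ref = smooth_image(7, shape=(96, 128))
        frame = subpixel_shift(ref, 0.0, 2.0)
        field = estimate_motion_field(frame, ref)
        # independent oracle: windowed cross-correlation shift estimate,
        # same backward convention as the field
        dy_o, dx_o = register_translation(frame, ref)
        assert abs(np.median(field.dx) - dx_o) < 0.25
        assert abs(np.median(field.dy) - dy_o) < 0.25
        assert abs(np.median(field.dx) - 2.0) < 0.25

    def test_large_lambda_gives_smoother_field(self):
        ref = smooth_image(9, shape=(64, 96))
        rng = np.random.default_rng(4)
        yy, xx = np.mgrid[0:64, 0:96].astype(float)
        dy = 1.0 * np.sin(yy * np.pi / 63) * np.sin(xx * np.pi / 95)
        frame = ndimage.map_coordinates(ref, np.stack([yy - dy, xx]), order=1, mode="nearest")

        def grad_energy(f):
            gy, gx = np.gradient(f.dy)
            hy, hx = np.gradient(f.dx)
            return (gy**2 + gx**2 + hy**2 + hx**2).sum()

        f_default = estimate_motion_field(frame, ref, OpticFlowParams(lambda_smooth=800))
        f_stiff = estimate_motion_field(frame, ref, OpticFlowParams(lambda_smooth=1e6))
        assert grad_energy(f_stiff) < grad_energy(f_default)

    def test_nonfinite_input_rejected(self):
        img = smooth_image(2)
        bad = img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            estimate_motion_field(bad, img)

    def test_energy_nonincreasing_over_inner_iterations(self):
        ref = smooth_image(11)
        frame = subpixel_shift(ref, 0.4, 0.9)
        gy, gx = np.gradient(frame)
        it = frame - ref
        u = np.zeros_like(ref)
        v = np.zeros_like(ref)
        zeros = np.zeros_like(ref)
        energies = []
        for _ in range(40):
            energies.append(_hs_flow_energy(gx, gy, it, u, v, 800.0, zeros, zeros))
            u, v = _hs_iterate(gx, gy, it, u, v, 800.0, 1, 0.0)
        assert np.all(np.diff(energies) <= 1e-9)


class TestWarpBilinear:
    def test_zero_field_is_identity(self):
        img = smooth_image(1)
        field = MotionField(np.zeros_like(img), np.zeros_like(img))
        np.testing.assert_array_equal(warp_bilinear(img, field), img)

    def test_constant_integer_field_shifts_columns(self):
        img = smooth_image(2)
        field = MotionField(np.zeros_like(img), np.full_like(img, 2.0))
        out = warp_bilinear(img, field)
        # output(p) = img(p + 2 in x): interior matches a 2-column shift
        np.testing.assert_allclose(out[:, :-2], img[:, 2:])

    def test_round_trip_small_field(self):
        img = smooth_image(3)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
        dy = 1.5 * np.sin(yy * np.pi / 63) * np.sin(xx * np.pi / 95)
        dx = 1.0 * np.sin(2 * yy * np.pi / 63) * np.sin(xx * np.pi / 95)
        field = MotionField(dy, dx)
        inverse = MotionField(-dy, -dx)
        back = warp_bilinear(warp_bilinear(img, field), inverse)
        interior = (slice(4, -4), slice(4, -4))
        err = np.abs(back[interior] - img[interior]).mean()
        assert err < 0.01 * np.ptp(img)

    def test_shape_mismatch_rejected(self):
        img = smooth_image(4)
        with pytest.raises(ValueError):
            warp_bilinear(img, MotionField(np.zeros((8, 8)), np.zeros((8, 8))))


class TestCorrectTwoChannel:
    def test_recovers_true_fields(self, corrected_movie):
        """Mean endpoint error against generator truth below 0.5 px."""
        _, _, fields, truth = corrected_movie
        epe = [
            np.hypot(f.dy - t.dy, f.dx - t.dx).mean()
            for f, t in zip(fields[1:], truth.true_motion_fields[1:])
        ]
        assert np.mean(epe) < 0.5

    def test_correction_improves_reference_correlation(self, moving_movie, corrected_movie):
        _, red, _, _ = moving_movie
        red_c, _, _, _ = corrected_movie
        ref_raw = red.data[0].ravel()
        ref_cor = red_c.data[0].ravel()
        for t in range(1, red.n_frames):
            c_raw = np.corrcoef(red.data[t].ravel(), ref_raw)[0, 1]
            c_cor = np.corrcoef(red_c.data[t].ravel(), ref_cor)[0, 1]
            assert c_cor >= c_raw

    def test_constant_green_stays_constant(self):
        from flyvnc.registration import correct_two_channel
        from flyvnc.synthetic import ConnectiveMovieSpec, generate_connective_movie

        spec = ConnectiveMovieSpec(
            n_frames=4, motion_amplitude=3.0, nonrigid_amplitude=1.0,
            noise_sd=0.0, seed=5,
        )
        red, green, _ = generate_connective_movie(spec)
        const = green.copy_with(np.full_like(green.data, 50.0))
        _, green_c, _ = correct_two_channel(red, const)
        assert np.abs(green_c.data - 50.0).max() < 0.5  # 1% of value

    def test_length_mismatch_rejected(self):
        from flyvnc.registration import correct_two_channel

        a = FrameStack(np.zeros((2, 16, 16)) + 1.0)
        b = FrameStack(np.zeros((3, 16, 16)) + 1.0)
        with pytest.raises(ValueError):
            correct_two_channel(a, b)


class TestRegisterTranslation:
    def test_identical_images(self):
        img = smooth_image(6)
        assert register_translation(img, img) == (0.0, 0.0)

    def test_recovers_known_shift(self):
        ref = smooth_image(8, shape=(96, 128))
        shifted = subpixel_shift(ref, -4.0, 7.0)
        dy, dx = register_translation(shifted, ref)
        assert abs(dy - (-4.0)) < 0.1
        assert abs(dx - 7.0) < 0.1

    def test_constant_image_warns(self):
        with pytest.warns(UserWarning):
            out = register_translation(np.ones((32, 32)), smooth_image(1, (32, 32)))
        assert out == (0.0, 0.0)
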