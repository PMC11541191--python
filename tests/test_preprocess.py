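"""Alignment, bleedthrough subtraction, cropping and RL deconvolution."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from mitoquant import preprocess
from mitoquant.optics import gaussian_psf
from mitoquant.preprocess import (
    RigidTransformSet,
    _transform_slice,
    align_stack,
    apply_transforms,
    crop_roi,
    rl_deconvolve,
    subtract_bleedthrough,
)


def _blob_slice(shape=(72, 84), seed=0):
    """A smooth, structured test slice (sum of Gaussian blobs)."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(6):
        cy, cx = rng.uniform(15, shape[0] - 15), rng.uniform(15, shape[1] - 15)
        s = rng.uniform(2.5, 6.0)
        img += rng.uniform(50, 200) * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)
        )
    return img


class TestAlignStack:
    def test_aligned_stack_yields_identity_transforms(self):
        base = _blob_slice()
        stack = np.stack([base] * 5)
        _, tset = align_stack(stack)
        assert np.abs(tset.transforms[:, 1:]).max() < 0.1
        assert np.abs(tset.transforms[:, 0]).max() < 0.1

    def test_recovers_injected_per_slice_shifts(self):
        """Known rigid shifts recovered within 0.5 px on an identical-content stack."""
        base = _blob_slice(seed=3)
        truth = np.array(
            [[0.0, 0.0, 0.0], [0.4, 1.5, -2.0], [-0.6, -2.5, 1.0], [0.2, 3.0, 2.5]]
        )
        stack = np.stack(
            [_transform_slice(base, ang, dy, dx) for ang, dy, dx in truth]
        )
        _, tset = align_stack(stack, reference_slice=0)
        # recovered transforms should invert the injected motion
        inv = tset.transforms
        for i in range(1, 4):
            assert abs(inv[i, 1] + truth[i, 1]) < 0.5
            assert abs(inv[i, 2] + truth[i, 2]) < 0.5

    def test_checkerboard_shift_matches_phase_correlation_oracle(self):
        base = np.kron(
            np.indices((9, 11)).sum(axis=0) % 2, np.ones((8, 8))
        ).astype(float)
        base = ndimage.gaussian_filter(base * 100, 1.2)
        moved = _transform_slice(base, 0.0, 3.0, -2.0)
        stack = np.stack([base, moved])
        _, tset = align_stack(stack, reference_slice=0)
        oracle, *_ = phase_cross_correlation(
            base, moved, upsample_factor=50, normalization=None
        )
        assert tset.transforms[1, 1] == pytest.approx(-3.0, abs=0.25)
        assert tset.transforms[1, 2] == pytest.approx(2.0, abs=0.25)
        assert tset.transforms[1, 1] == pytest.approx(oracle[0], abs=0.25)

    def test_empty_slice_gets_identity_with_warning(self):
        base = _blob_slice()
        stack = np.stack([base, np.zeros_like(base), base])
        with pytest.warns(UserWarning, match="empty"):
            _, tset = align_stack(stack, reference_slice=0)
        np.testing.assert_array_equal(tset.transforms[1], 0.0)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            align_stack(_blob_slice()[None])


class TestApplyTransforms:
    def test_identity_nearest_neighbour_is_bitwise_equal(self):
        stack = (np.random.default_rng(0).uniform(0, 255, (4, 20, 24))).astype(
            np.uint16
        )
        tset = RigidTransformSet(np.zeros((4, 3)))
        out = apply_transforms(stack, tset, order=0)
        np.testing.assert_array_equal(out, stack)

    def test_round_trip_bounded_by_interpolation_error(self):
        base = _blob_slice(seed=5)
        stack = np.stack([base] * 3)
        tset = RigidTransformSet(
            np.array([[0.5, 2.0, -1.5], [-0.3, -1.0, 2.5], [0.0, 3.0, 3.0]])
        )
        fwd = apply_transforms(stack, tset)
        back = apply_transforms(fwd, tset.inverse())
        inner = (slice(None), slice(8, -8), slice(8, -8))
        assert np.abs(back[inner] - stack[inner]).max() < 0.05 * base.max()

    def test_slice_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="transforms"):
            apply_transforms(np.zeros((3, 8, 8)), RigidTransformSet(np.zeros((2, 3))))

    def test_red_transforms_restore_green_geometry(self, small_scene, acq_psf):
        """Transforms estimated on red, applied to green, undo the shared jitter.

        The jittered green stack aligned with the *red* channel's transform
        set should cross-correlate with the jitter-free green ground truth
        at (or next to) zero lag on every informative slice.
        """
        from mitoquant import synthgen
        from mitoquant._fft import FFTConvolver

        sim = synthgen.simulate_timeseries(
            small_scene,
            synthgen.BleachSchedule(fluctuation_sd=0.0, n_timepoints=2),
            psf=acq_psf,
            jitter=synthgen.JitterModel(),
            noise=None,
            rng_seed=21,
        )
        red, green = sim.stack.data[0, 0], sim.stack.data[0, 1]
        _, tset = align_stack(red)
        green_al = apply_transforms(green, tset)
        truth = FFTConvolver(acq_psf, small_scene.green.shape).convolve(
            small_scene.green
        )
        n_y, n_x = truth.shape[1:]
        lags = []
        for z in range(truth.shape[0]):
            if truth[z].max() < 0.25 * truth.max():
                continue  # dim slice: green correlation uninformative
            g = green_al[z] - green_al[z].mean()
            t = truth[z] - truth[z].mean()
            corr = np.fft.irfft2(np.fft.rfft2(g) * np.conj(np.fft.rfft2(t)))
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            lags.append((min(py, n_y - py), min(px, n_x - px)))
        assert len(lags) >= 5
        good = sum(dy <= 2 and dx <= 2 for dy, dx in lags)
        assert good >= 0.8 * len(lags), f"misaligned slices: {lags}"


class TestSubtractBleedthrough:
    def test_zero_red_leaves_green_unchanged(self):
        green = np.arange(24, dtype=np.uint16).reshape(2, 3, 4)
        out = subtract_bleedthrough(green, np.zeros_like(green), 1.0)
        np.testing.assert_array_equal(out, green)
        assert out.dtype == np.uint16

    def test_full_subtraction_clips_at_zero(self):
        green = np.full((2, 2), 10, dtype=np.uint16)
        red = np.full((2, 2), 30, dtype=np.uint16)
        out = subtract_bleedthrough(green, red, 1.0)
        assert out.dtype == np.uint16
        np.testing.assert_array_equal(out, 0)

    def test_subtraction_idempotent_when_red_zero(self):
        green = np.random.default_rng(1).integers(0, 999, (3, 8, 8)).astype(np.uint16)
        zero = np.zeros_like(green)
        once = subtract_bleedthrough(green, zero, 0.12)
        twice = subtract_bleedthrough(once, zero, 0.12)
        np.testing.assert_array_equal(once, twice)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            subtract_bleedthrough(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_twelve_percent_recovers_mito_signal_within_5pc(
        self, small_scene, acq_psf
    ):
        """With 8% bleedthrough in, subtracting 12% keeps integrated density."""
        from mitoquant import synthgen

        sim = synthgen.simulate_timeseries(
            small_scene,
            synthgen.BleachSchedule(fluctuation_sd=0.0, n_timepoints=2),
            psf=acq_psf,
            bleedthrough_fraction=0.08,
            jitter=None,
            noise=None,
            rng_seed=0,
        )
        red, green = sim.stack.data[0, 0], sim.stack.data[0, 1]
        cleaned = subtract_bleedthrough(green, red, 0.12)
        from mitoquant._fft import FFTConvolver

        truth = FFTConvolver(acq_psf, small_scene.green.shape).convolve(
            small_scene.green
        )
        assert cleaned.sum() == pytest.approx(truth.sum(), rel=0.05)


class TestCropRoi:
    def test_full_extent_box_copies_stack(self):
        stack = np.random.default_rng(0).random((4, 6, 8))
        out = crop_roi(stack, ((0, 4), (0, 6), (0, 8)))
        np.testing.assert_array_equal(out, stack)
        assert out.base is None  # a copy, not a view

    def test_single_voxel_box(self):
        stack = np.arange(24.0).reshape(2, 3, 4)
        out = crop_roi(stack, ((1, 2), (2, 3), (3, 4)))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == stack[1, 2, 3]

    def test_crop_plus_complement_conserves_total(self):
        stack = np.random.default_rng(2).random((6, 10, 12))
        left = crop_roi(stack, ((0, 6), (0, 10), (0, 5)))
        right = crop_roi(stack, ((0, 6), (0, 10), (5, 12)))
        assert left.sum() + right.sum() == pytest.approx(stack.sum())

    def test_empty_box_rejected(self):
        with pytest.raises(ValueError, match="empty or out-of-bounds"):
            crop_roi(np.zeros((4, 4, 4)), ((2, 2), (0, 4), (0, 4)))


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 100, (5, 16, 16))
        delta = np.zeros((3, 3, 3))
        delta[1, 1, 1] = 1.0
        out = rl_deconvolve(stack, delta, iterations=7)
        assert np.allclose(out, stack, rtol=1e-3, atol=1e-2)

    def test_flux_conserved_within_one_percent(self, deconv_psf):
        img = np.zeros((9, 48, 48))
        img[4, 20:28, 18:30] = 200.0
        from mitoquant._fft import FFTConvolver

        blurred = np.clip(FFTConvolver(deconv_psf, img.shape).convolve(img), 0, None)
        restored = rl_deconvolve(blurred, deconv_psf, iterations=20)
        assert restored.sum() == pytest.approx(blurred.sum(), rel=0.01)

    def test_sharpens_blurred_capsule_toward_truth(self, deconv_psf):
        """Lateral FWHM shrinks after 20 iterations and approaches the true width."""
        img = np.zeros((9, 64, 64))
        img[4, 30:34, 12:52] = 100.0  # 4-px wide bar (~0.17 um)
        from mitoquant._fft import FFTConvolver

        blurred = np.clip(FFTConvolver(deconv_psf, img.shape).convolve(img), 0, None)
        restored = rl_deconvolve(blurred, deconv_psf, iterations=20)

        def fwhm(profile):
            half = profile.max() / 2.0
            above = np.nonzero(profile >= half)[0]
            return above[-1] - above[0] + 1

        w_blur = fwhm(blurred[4, :, 32])
        w_rest = fwhm(restored[4, :, 32])
        assert w_rest < w_blur
        assert abs(w_rest - 4) <= abs(w_blur - 4)

    def test_kl_divergence_nonincreasing(self, deconv_psf):
        """RL monotonically improves the Poisson likelihood of the blur model."""
        rng = np.random.default_rng(4)
        img = np.zeros((7, 32, 32))
        img[3, 10:20, 10:20] = rng.uniform(50, 150, (10, 10))
        from mitoquant._fft import FFTConvolver

        conv = FFTConvolver(deconv_psf, img.shape)
        observed = np.clip(conv.convolve(img), 1e-9, None)

        def kl(est):
            model = np.clip(conv.convolve(est), 1e-9, None)
            return float(np.sum(model - observed * np.log(model)))

        prev = np.inf
        for it in (1, 3, 6, 12, 20):
            d = kl(rl_deconvolve(observed, deconv_psf, iterations=it))
            assert d <= prev + 1e-3 * abs(prev)
            prev = d

    def test_matches_reference_implementation(self):
        """Agrees with the scikit-image RL oracle away from the boundary."""
        from skimage.restoration import richardson_lucy as sk_rl

        rng = np.random.default_rng(8)
        img = np.zeros((32, 32))
        img[10:22, 8:25] = rng.uniform(20, 80, (12, 17))
        psf = gaussian_psf(
            fwhm_lateral_um=0.12, fwhm_axial_um=0.12,
            voxel_size=(0.0425, 0.0425, 0.0425), shape=(1, 9, 9),
        )[0]
        blurred = ndimage.convolve(img, psf, mode="constant")
        ours = rl_deconvolve(blurred, psf, iterations=10)
        theirs = sk_rl(blurred / blurred.max(), psf, num_iter=10, clip=False)
        theirs *= blurred.max()
        inner = (slice(8, -8), slice(8, -8))
        denom = np.abs(theirs[inner]).max()
        assert np.abs(ours[inner] - theirs[inner]).max() / denom < 0.05

    def test_invalid_inputs_rejected(self, deconv_psf):
        with pytest.raises(ValueError, match="iterations"):
            rl_deconvolve(np.ones((3, 8, 8)), deconv_psf, iterations=0)
        with pytest.raises(ValueError, match="sum to 1"):
            rl_deconvolve(np.ones((3, 8, 8)), np.ones((3, 3, 3)))


class TestTransformSetIO:
    def test_text_round_trip(self, tmp_path):
        tset = RigidTransformSet(
            np.array([[0.1, 1.0, -2.0], [-0.4, 0.5, 0.25]]), reference_slice=1
        )
        path = tset.to_text(tmp_path / "transforms.txt")
        loaded = RigidTransformSet.from_text(path)
        np.testing.assert_allclose(loaded.transforms, tset.transforms)
        assert loaded.reference_slice == 1
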