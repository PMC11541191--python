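"""Global thresholds, the surface-style chain, ROI masking, object metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant import segmentation as seg
from mitoquant.rois import ROISet
from mitoquant.segmentation import (
    global_threshold,
    imagej_default_index,
    imaris_like_surface,
    isodata_threshold_index,
    mask_outside_rois,
    measure_objects,
    pixels_per_um2,
)


def _intermeans_fixed_points(counts):
    """Brute-force scan: integer levels k satisfying the intermeans condition.

    k is a fixed point when the intermeans midpoint of the partition
    (bins <= k | bins > k) falls within (k, k+1]."""
    counts = np.asarray(counts, dtype=float)
    idx = np.arange(len(counts))
    out = []
    for k in range(len(counts) - 1):
        below, above = counts[: k + 1], counts[k + 1 :]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mid = (
            (below * idx[: k + 1]).sum() / below.sum()
            + (above * idx[k + 1 :]).sum() / above.sum()
        ) / 2.0
        if k < mid <= k + 1:
            out.append(k)
    return out


class TestIsodata:
    def test_two_delta_peaks_threshold_at_midpoint(self):
        """Histogram peaks at 10 and 200: the intermeans fixed point is 105."""
        img = np.array([[10.0] * 60 + [200.0] * 40])
        res = global_threshold(img, "isodata")
        assert res.value == pytest.approx(105.0, abs=0.5)
        assert int((img > res.value).sum()) == 40

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_fixed_point_scan(self, seed):
        """Converged Isodata level is a brute-force intermeans fixed point."""
        rng = np.random.default_rng(seed)
        # mixture of two broad 8-bit modes plus noise floor
        lo = rng.normal(rng.uniform(30, 80), rng.uniform(5, 20), 4000)
        hi = rng.normal(rng.uniform(140, 220), rng.uniform(5, 30), rng.integers(500, 4000))
        img = np.clip(np.concatenate([lo, hi]), 0, 255).astype(np.uint8)
        counts = np.bincount(img.ravel(), minlength=256)
        t_idx = isodata_threshold_index(counts)
        fixed = _intermeans_fixed_points(counts)
        assert fixed, "oracle found no fixed point"
        assert int(np.floor(t_idx)) in fixed

    def test_scaling_invariance_exact(self):
        """threshold(s*I) = s*threshold(I); foreground count unchanged."""
        rng = np.random.default_rng(1)
        img = np.concatenate(
            [rng.gamma(2.0, 50.0, 20000), rng.normal(3000, 200, 3000)]
        ).reshape(100, -1)
        base = global_threshold(img, "isodata")
        n_base = int((img > base.value).sum())
        for s in (0.8, 0.7, 1.3):
            scaled = global_threshold(s * img, "isodata")
            assert scaled.value == pytest.approx(s * base.value, rel=1e-9)
            assert int((s * img > scaled.value).sum()) == n_base

    @given(st.floats(0.5, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_scaling_invariance_property(self, s):
        rng = np.random.default_rng(7)
        img = rng.gamma(1.5, 100.0, (40, 40))
        base = global_threshold(img, "isodata")
        scaled = global_threshold(s * img, "isodata")
        assert scaled.value == pytest.approx(s * base.value, rel=1e-6)
        assert int((s * img > scaled.value).sum()) == int((img > base.value).sum())

    def test_constant_image_has_no_threshold(self):
        with pytest.raises(ValueError, match="no threshold exists"):
            global_threshold(np.full((4, 4), 7.0), "isodata")


class TestOtherAlgorithms:
    def test_otsu_separates_perfect_bimodal_exactly(self):
        img = np.zeros((10, 10))
        img.ravel()[:37] = 255.0
        res = global_threshold(img, "otsu")
        assert int((img > res.value).sum()) == 37

    def test_imagej_default_near_isodata_on_bimodal(self):
        rng = np.random.default_rng(3)
        img = np.concatenate(
            [rng.normal(40, 8, 6000), rng.normal(190, 15, 2000)]
        ).clip(0, 255).astype(np.uint8)
        iso = global_threshold(img, "isodata")
        ijd = global_threshold(img, "imagej_default")
        assert abs(ijd.bin_index - iso.bin_index) <= 5

    def test_imagej_default_ignores_extreme_bins(self):
        counts = np.zeros(256, dtype=int)
        counts[0] = 100000          # erased background spike
        counts[40] = 500
        counts[200] = 500
        level = imagej_default_index(counts)
        assert 40 < level < 200

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            global_threshold(np.arange(16.0).reshape(4, 4), "magic")


class TestMeasureObjects:
    def test_pixels_per_um2_constant(self):
        assert pixels_per_um2(0.0425) == 553.63

    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        res = measure_objects(mask, voxel_size=(0.1, 0.1, 0.1), mode="3d")
        assert res.total_quantity == 1
        assert res.objects.volume_um3.iloc[0] == pytest.approx(0.001)

    def test_digitised_ball_is_nearly_spherical(self):
        r = 10
        zz, yy, xx = np.mgrid[-14:15, -14:15, -14:15]
        ball = zz**2 + yy**2 + xx**2 <= r**2
        res = measure_objects(
            ball, voxel_size=(0.1, 0.1, 0.1), mode="3d", compute_sphericity=True
        )
        assert len(res.objects) == 1
        assert res.objects.sphericity.iloc[0] >= 0.95

    def test_total_quantity_sums_object_counts(self, small_scene):
        res = measure_objects(
            small_scene.labels > 0, small_scene.spec.voxel_size, mode="3d"
        )
        assert res.total_quantity == res.objects.voxel_count.sum()
        assert res.total_quantity == small_scene.true_foreground_voxels

    def test_2d_mode_sums_per_slice_areas(self):
        mask = np.zeros((2, 8, 8), dtype=bool)
        mask[0, 1:3, 1:3] = True      # 4 px
        mask[1, 5:8, 5:8] = True      # 9 px
        res = measure_objects(mask, voxel_size=(0.13, 0.0425, 0.0425), mode="2d")
        assert res.total_quantity == 13
        assert res.objects.area_um2.sum() == pytest.approx(13 / 553.63)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            measure_objects(np.zeros((2, 2, 2), dtype=bool), mode="4d")

    def test_sphericity_below_one_for_elongated_object(self):
        rod = np.zeros((5, 5, 40), dtype=bool)
        rod[2, 2, 2:38] = True
        res = measure_objects(
            rod, voxel_size=(0.1, 0.1, 0.1), mode="3d", compute_sphericity=True
        )
        assert 0 < res.objects.sphericity.iloc[0] < 0.7


def _square_roi(z_range, lo, hi):
    poly = np.array([[lo, lo], [lo, hi], [hi, hi], [hi, lo]], dtype=float)
    return ROISet(polygons={z: [poly.copy()] for z in z_range})


class TestMaskOutsideRois:
    def test_whole_frame_roi_keeps_mask(self):
        mask = np.random.default_rng(0).random((4, 20, 20)) > 0.6
        rois = _square_roi(range(4), -1, 20)
        out = mask_outside_rois(mask, rois)
        assert out.sum() == mask.sum()

    def test_disjoint_roi_quantities_are_additive(self):
        mask = np.random.default_rng(1).random((3, 30, 30)) > 0.5
        whole = _square_roi(range(3), 0, 29)
        left = ROISet(
            polygons={
                z: [np.array([[0, 0], [0, 14.5], [29, 14.5], [29, 0]])]
                for z in range(3)
            }
        )
        right = ROISet(
            polygons={
                z: [np.array([[0, 14.5], [0, 29], [29, 29], [29, 14.5]])]
                for z in range(3)
            }
        )
        total = mask_outside_rois(mask, whole).sum()
        assert mask_outside_rois(mask, left).sum() + mask_outside_rois(
            mask, right
        ).sum() == pytest.approx(total, abs=60)  # boundary pixels only

    def test_roi_excluding_foreground_empties_mask(self):
        mask = np.zeros((3, 20, 20), dtype=bool)
        mask[1, 10:15, 10:15] = True
        rois = _square_roi([1], 0, 5)
        assert mask_outside_rois(mask, rois).sum() == 0

    def test_slices_outside_roi_range_dropped(self):
        mask = np.ones((6, 10, 10), dtype=bool)
        rois = _square_roi([2, 3], -1, 10)
        out = mask_outside_rois(mask, rois)
        assert out.shape[0] == 2

    def test_neighbour_object_outside_cell_removed(self, small_scene):
        from mitoquant import synthgen

        rois = synthgen.cell_rois(small_scene, margin_um=0.3)
        mask = small_scene.labels > 0
        # plant an intruding object outside the cell, in a corner
        intruder = mask.copy()
        intruder[mask.shape[0] // 2, :6, :6] = True
        kept = mask_outside_rois(intruder, rois)
        z0, _ = rois.slice_range
        assert kept.sum() == mask_outside_rois(mask, rois).sum()
        assert kept.sum() == small_scene.true_foreground_voxels


class TestImarisLikeSurface:
    def test_recovers_capsules_within_15_percent(self, small_scene):
        """Flat background + bright capsules: voxel count near ground truth."""
        result, thr = imaris_like_surface(
            small_scene.green, voxel_size=small_scene.spec.voxel_size
        )
        truth = small_scene.true_foreground_voxels
        assert result.total_quantity == pytest.approx(truth, rel=0.15)

    def test_constant_image_error_path(self):
        with pytest.raises(ValueError, match="no threshold exists"):
            imaris_like_surface(np.full((6, 24, 24), 5.0))

    def test_subvoxel_grain_smoothing_is_noop(self, small_scene, acq_psf):
        """1 nm grain on 42.5 nm voxels: identical to skipping the smoothing."""
        from scipy import ndimage as ndi

        from mitoquant._fft import FFTConvolver

        blurred = FFTConvolver(acq_psf, small_scene.green.shape).convolve(
            small_scene.green
        )
        vs = small_scene.spec.voxel_size
        result, thr = imaris_like_surface(blurred, voxel_size=vs, grain_size_um=0.001)
        sigma = [0.319 / v for v in vs]
        baseline = ndi.gaussian_filter(blurred, sigma=sigma)
        cleaned = np.clip(blurred - baseline, 0, None)
        manual_thr = global_threshold(cleaned, "isodata")
        assert thr.value == pytest.approx(manual_thr.value)
        assert result.total_quantity == int((cleaned > manual_thr.value).sum())

    def test_roi_box_outside_stack_rejected(self):
        with pytest.raises(ValueError, match="roi_box"):
            imaris_like_surface(
                np.random.default_rng(0).random((4, 8, 8)),
                roi_box=((6, 6), (0, 8), (0, 8)),
            )
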