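"""Intensity normalization, cropping, resampling, patch planning/stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneeforge.core import CTVolume, ConfigurationError, DataQualityError, LabelVolume
from kneeforge.preprocessing import (
    NormalizationParams,
    crop_to_label_extent,
    extract_patches,
    normalize_intensity,
    pad_to_patch,
    plan_patches,
    rescale_to_hu,
    resample_fixed,
    stitch_patches,
    strip_padding,
    uncrop,
)


def vol(arr, **kw):
    return CTVolume(np.asarray(arr, dtype=float), **kw)


class TestRescaleToHU:
    @pytest.mark.parametrize(
        "raw,slope,intercept,expected",
        [(0.0, 1.0, -1024.0, -1024.0), (1000.0, 1.0, 0.0, 1000.0),
         (512.0, 2.0, -1024.0, 0.0)],
    )
    def test_affine_examples(self, raw, slope, intercept, expected):
        out = rescale_to_hu(vol(np.full((2, 2, 2), raw)), slope, intercept)
        assert np.allclose(out.voxels, expected)

    def test_missing_parameters_name_the_dicom_tags(self):
        with pytest.raises(ConfigurationError, match="0028,105"):
            rescale_to_hu(vol(np.zeros((2, 2, 2))), None, None)


class TestNormalizeIntensity:
    @pytest.mark.parametrize(
        "hu,expected",
        [(2500.0, 1.0), (3000.0, 1.0), (-1024.0, 0.0), (-2000.0, 0.0),
         (738.0, 0.5)],  # (738 + 1024) / 3524
    )
    def test_clip_shift_scale(self, hu, expected):
        out = normalize_intensity(vol(np.full((2, 2, 2), hu)))
        assert np.allclose(out.voxels, expected)

    def test_range_width_is_3524(self):
        assert NormalizationParams().range_width == 3524.0

    def test_rejects_non_finite(self):
        bad = vol(np.array([[[np.nan, 0.0], [0.0, 0.0]], [[0.0] * 2] * 2]))
        with pytest.raises(DataQualityError, match="non-finite"):
            normalize_intensity(bad)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-3000, 4000, allow_nan=False), min_size=2, max_size=16))
    def test_monotone_and_bounded(self, values):
        arr = np.sort(np.asarray(values)).reshape(1, 1, -1)
        out = normalize_intensity(vol(arr)).voxels.ravel()
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_idempotent_on_normalized_data_reexpressed_in_hu(self):
        rng = np.random.default_rng(0)
        hu = vol(rng.uniform(-1024, 2500, (4, 4, 4)))
        once = normalize_intensity(hu)
        p = NormalizationParams()
        back_in_hu = vol(once.voxels * p.range_width + p.clip_lo)
        twice = normalize_intensity(back_in_hu)
        assert np.allclose(once.voxels, twice.voxels)


class TestCrop:
    def test_slab_bounds(self):
        lab = np.zeros((30, 8, 8), dtype=np.int16)
        lab[10:21] = 1
        ct = vol(np.random.default_rng(0).random((30, 8, 8)))
        _, _, rec = crop_to_label_extent(ct, LabelVolume(lab), margin=0)
        assert rec.lo[0] == 10 and rec.hi[0] == 20

    def test_all_foreground_is_identity(self):
        lab = np.ones((5, 6, 7), dtype=np.int16)
        ct = vol(np.zeros((5, 6, 7)))
        ct_c, lab_c, rec = crop_to_label_extent(ct, LabelVolume(lab))
        assert ct_c.shape == (5, 6, 7)
        assert rec.lo == (0, 0, 0)

    def test_single_voxel_with_margin(self):
        lab = np.zeros((12, 12, 12), dtype=np.int16)
        lab[5, 6, 7] = 1
        ct = vol(np.zeros((12, 12, 12)))
        _, _, rec = crop_to_label_extent(ct, LabelVolume(lab), margin=2)
        assert rec.lo == (3, 4, 5) and rec.hi == (7, 8, 9)

    def test_empty_labels_error(self):
        with pytest.raises(DataQualityError, match="no foreground"):
            crop_to_label_extent(vol(np.zeros((3, 3, 3))),
                                 LabelVolume(np.zeros((3, 3, 3), dtype=np.int16)))

    def test_crop_uncrop_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            shape = tuple(rng.integers(6, 20, 3))
            lab = np.zeros(shape, dtype=np.int16)
            n = rng.integers(1, 6)
            idx = tuple(rng.integers(0, s, n) for s in shape)
            lab[idx] = 1
            ct = vol(rng.random(shape))
            ct_c, _, rec = crop_to_label_extent(ct, LabelVolume(lab), margin=int(rng.integers(0, 3)))
            restored = uncrop(ct_c.voxels, rec)
            assert np.array_equal(restored[rec.slices()], ct.voxels[rec.slices()])

    def test_origin_shifts_with_crop(self):
        lab = np.zeros((10, 10, 10), dtype=np.int16)
        lab[4:7, 2:5, 3:6] = 1
        ct = CTVolume(np.zeros((10, 10, 10)), spacing=(2, 1, 1), origin=(5, 5, 5))
        ct_c, _, rec = crop_to_label_extent(ct, LabelVolume(lab))
        assert ct_c.origin == (5 + 4 * 2, 5 + 2, 5 + 3)


class TestResampleFixed:
    def test_constant_preserved(self):
        out = resample_fixed(vol(np.full((10, 12, 14), 3.5)), (8, 8, 8))
        assert out.shape == (8, 8, 8)
        assert np.allclose(out.voxels, 3.5)

    def test_identity_is_bit_exact(self):
        rng = np.random.default_rng(3)
        v = vol(rng.random((16, 16, 16)))
        out = resample_fixed(v, (16, 16, 16))
        assert np.array_equal(out.voxels, v.voxels)

    def test_label_downsample_volume_scaling(self):
        # centered cube spanning half the width: downsample x2 keeps the
        # foreground fraction, so counts scale by 1/8 (up to a 1-voxel shell)
        n = 64
        lab = np.zeros((n, n, n), dtype=np.int16)
        lab[16:48, 16:48, 16:48] = 1
        out = resample_fixed(LabelVolume(lab), (32, 32, 32), is_label=True)
        assert set(np.unique(out.voxels)) <= {0, 1}
        count = int((out.voxels == 1).sum())
        expected = 32**3 // 8
        shell = 6 * 16 * 16  # one-voxel shell of the downsampled cube
        assert abs(count - expected) <= shell

    def test_spacing_rescaled(self):
        out = resample_fixed(CTVolume(np.zeros((20, 20, 20)), spacing=(1, 1, 1)), (10, 10, 10))
        assert np.allclose(out.spacing, (2, 2, 2))

    def test_degenerate_axis_error(self):
        with pytest.raises(DataQualityError):
            resample_fixed(vol(np.zeros((1, 8, 8))), (8, 8, 8))


class TestPlanPatches:
    @pytest.mark.parametrize(
        "length,starts",
        [(160, [0]), (200, [0, 40]), (430, [0, 135, 270])],
    )
    def test_axis_starts(self, length, starts):
        grid = plan_patches((length, 160, 160), 160)
        assert grid.starts[0] == starts

    def test_overlap_reported(self):
        grid = plan_patches((200, 160, 160), 160)
        assert grid.overlaps[0] == 120

    def test_small_axis_error_suggests_padding(self):
        with pytest.raises(ConfigurationError, match="pad"):
            plan_patches((100, 200, 200), 160)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.tuples(st.integers(16, 90), st.integers(16, 90), st.integers(16, 90)))
    def test_full_coverage(self, shape):
        grid = plan_patches(shape, 16)
        covered = np.zeros(shape, dtype=bool)
        P = grid.patch_size
        for (i, j, k) in grid.placements():
            assert i + P[0] <= shape[0] and j + P[1] <= shape[1] and k + P[2] <= shape[2]
            covered[i:i + P[0], j:j + P[1], k:k + P[2]] = True
        assert covered.all()


class TestStitch:
    def test_constant_blocks(self):
        grid = plan_patches((24, 16, 16), 16)
        blocks = [np.full((16, 16, 16), 2.5) for _ in grid.placements()]
        out = stitch_patches(blocks, grid)
        assert np.allclose(out, 2.5)

    def test_non_overlapping_is_exact_copy(self):
        rng = np.random.default_rng(0)
        v = rng.random((32, 16, 16))
        grid = plan_patches(v.shape, 16)
        assert grid.overlaps == (0, 0, 0)
        out = stitch_patches(extract_patches(v, grid), grid)
        assert np.array_equal(out, v)

    def test_two_patch_overlap_mean(self):
        grid = plan_patches((200, 16, 16), (160, 16, 16))
        blocks = [np.zeros((160, 16, 16)), np.ones((160, 16, 16))]
        out = stitch_patches(blocks, grid)
        assert np.allclose(out[:40], 0.0)
        assert np.allclose(out[40:160], 0.5)   # 120-voxel overlap
        assert np.allclose(out[160:], 1.0)

    def test_extract_then_stitch_identity(self):
        rng = np.random.default_rng(5)
        v = rng.random((40, 28, 36))
        grid = plan_patches(v.shape, 16)
        out = stitch_patches(extract_patches(v, grid), grid)
        assert np.abs(out - v).max() < 1e-6

    def test_block_count_mismatch_error(self):
        grid = plan_patches((32, 16, 16), 16)
        with pytest.raises(DataQualityError, match="blocks"):
            stitch_patches([np.zeros((16, 16, 16))], grid)


class TestPadding:
    def test_pad_then_strip_round_trip(self):
        v = np.random.default_rng(0).random((10, 40, 20))
        padded, pads = pad_to_patch(v, 16)
        assert all(s >= 16 for s in padded.shape)
        assert np.array_equal(strip_padding(padded, pads), v)
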