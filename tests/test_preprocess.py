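"""Resampling, pad/crop, normalisation, redundant class, and inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eatseg.ct_io import CTVolume, SegmentationMask, GridMismatchError
from eatseg.preprocess import (
    GridTransform,
    PreprocessConfig,
    apply_pipeline,
    clip_normalize,
    invert_to_native,
    make_redundant_class,
    pad_crop_center,
    resample_isotropic,
)
from eatseg.metrics import dice


class TestResampleIsotropic:
    def test_output_shape_arithmetic(self, rng):
        vol = CTVolume(rng.random((96, 96, 96)), (1.2, 1.2, 1.2))
        out = resample_isotropic(vol, 1.6)
        assert out.data.shape == (72, 72, 72)  # 96·1.2/1.6
        assert out.spacing == (1.6, 1.6, 1.6)

    def test_constant_volume_stays_constant(self, rng):
        for mode in ("trilinear", "nearest"):
            vol = CTVolume(np.full((20, 16, 12), 37.0), (2.0, 1.0, 3.0))
            out = resample_isotropic(vol, 1.6, mode)
            np.testing.assert_allclose(out.data, 37.0, atol=1e-5)

    def test_nearest_preserves_binary_values(self, rng):
        mask = SegmentationMask((rng.random((32, 32, 32)) > 0.5).astype(np.uint8), (2.0,) * 3)
        out = resample_isotropic(mask, 1.6, "nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_blob_physical_volume_approximately_conserved(self, rng):
        """count·spacing³ before vs after, 20 random blobby masks, <15% error."""
        for _ in range(20):
            center = rng.uniform(10, 22, size=3)
            radius = rng.uniform(6, 9)
            idx = np.indices((32, 32, 32))
            blob = (
                ((idx[0] - center[0]) ** 2 + (idx[1] - center[1]) ** 2
                 + (idx[2] - center[2]) ** 2) <= radius ** 2
            )
            mask = SegmentationMask(blob.astype(np.uint8), (2.0, 2.0, 2.0))
            out = resample_isotropic(mask, 1.6, "nearest")
            v_in = blob.sum() * 2.0 ** 3
            v_out = out.data.sum() * 1.6 ** 3
            assert abs(v_out - v_in) / v_in < 0.15

    def test_bad_spacing_rejected(self, rng):
        vol = CTVolume(rng.random((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


class TestPadCropCenter:
    def test_identity_when_already_cube(self, rng):
        vol = CTVolume(rng.random((16, 16, 16)), (1, 1, 1))
        out, t = pad_crop_center(vol, 16)
        np.testing.assert_array_equal(out.data, vol.data)
        assert t.pad_low == t.pad_high == t.crop_low == t.crop_high == (0, 0, 0)

    def test_pad_centers_content(self, rng):
        data = rng.random((100, 100, 100)).astype(np.float32)
        vol = CTVolume(data, (1, 1, 1))
        out, t = pad_crop_center(vol, 128, fill_value=-800.0)
        assert out.data.shape == (128, 128, 128)
        assert t.pad_low == t.pad_high == (14, 14, 14)
        assert out.data[14, 14, 14] == data[0, 0, 0]
        assert out.data[0, 0, 0] == -800.0

    def test_crop_matches_direct_slicing(self, rng):
        data = rng.random((150, 150, 150)).astype(np.float32)
        vol = CTVolume(data, (1, 1, 1))
        out, t = pad_crop_center(vol, 128)
        assert t.crop_low == t.crop_high == (11, 11, 11)
        np.testing.assert_array_equal(out.data, data[11:139, 11:139, 11:139])

    def test_odd_difference_splits_within_one(self, rng):
        vol = CTVolume(rng.random((13, 13, 13)), (1, 1, 1))
        out, t = pad_crop_center(vol, 16)
        for lo, hi in zip(t.pad_low, t.pad_high):
            assert abs(lo - hi) <= 1
            assert lo + hi == 3

    def test_transform_validates_exclusivity(self):
        with pytest.raises(ValueError):
            GridTransform(
                native_shape=(8, 8, 8), native_spacing=(1, 1, 1),
                resampled_shape=(8, 8, 8),
                pad_low=(1, 0, 0), crop_low=(1, 0, 0),
            )


class TestClipNormalize:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-800.0, 0.0), (1200.0, 1.0), (200.0, 0.5), (-2000.0, 0.0), (5000.0, 1.0)],
    )
    def test_default_window_values(self, hu, expected):
        vol = CTVolume(np.full((2, 2, 2), hu), (1, 1, 1))
        assert clip_normalize(vol).data[0, 0, 0] == pytest.approx(expected)

    def test_monotone_in_hu(self, rng):
        hu = np.sort(rng.uniform(-2000, 3000, size=64)).reshape(4, 4, 4)
        out = clip_normalize(CTVolume(hu, (1, 1, 1))).data.ravel()
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_window(self):
        vol = CTVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError):
            clip_normalize(vol, 100.0, -100.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        hu=st.lists(st.floats(-3000, 4000, allow_nan=False), min_size=8, max_size=8),
        lo=st.floats(-1000, 0),
        width=st.floats(10, 3000),
    )
    def test_output_in_unit_interval_and_order_preserving(self, hu, lo, width):
        vol = CTVolume(np.array(hu, dtype=np.float32).reshape(2, 2, 2), (1, 1, 1))
        out = clip_normalize(vol, lo, lo + width).data.ravel()
        assert np.all((out >= 0) & (out <= 1))
        order = np.argsort(hu, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-7)


class TestRedundantClass:
    def _toy(self, rng, nz=10):
        hu = rng.uniform(-400, 100, size=(8, 8, nz)).astype(np.float32)
        hu[2:5, 2:5, :] = -100.0  # fat-density column through all slices
        vol = CTVolume(hu, (1, 1, 1))
        peri = np.zeros((8, 8, nz), dtype=np.uint8)
        peri[3:6, 3:6, 2:8] = 1
        return vol, SegmentationMask(peri, (1, 1, 1))

    def test_matches_brute_force_oracle(self, rng):
        vol, peri = self._toy(rng)
        cfg = PreprocessConfig()
        labels = make_redundant_class(vol, peri, cfg)
        boundary = math.ceil(0.2 * 10)
        expected = np.zeros(vol.data.shape, dtype=np.uint8)
        for i in range(8):
            for j in range(8):
                for k in range(10):
                    if peri.data[i, j, k] == 1:
                        expected[i, j, k] = 1
                    elif k < boundary and -198 <= vol.data[i, j, k] <= -80:
                        expected[i, j, k] = 2
        np.testing.assert_array_equal(labels.data, expected)

    def test_redundant_restricted_to_inferior_slices(self, rng):
        vol, peri = self._toy(rng)
        labels = make_redundant_class(vol, peri, PreprocessConfig())
        assert np.any(labels.data[:, :, :2] == 2)
        assert not np.any(labels.data[:, :, 2:] == 2)

    def test_pericardium_takes_precedence(self):
        hu = np.full((4, 4, 10), -100.0)
        vol = CTVolume(hu, (1, 1, 1))
        peri = np.zeros((4, 4, 10), dtype=np.uint8)
        peri[1, 1, 0] = 1
        labels = make_redundant_class(vol, SegmentationMask(peri, (1, 1, 1)),
                                      PreprocessConfig())
        assert labels.data[1, 1, 0] == 1          # inside pericardium, slice 0
        assert labels.data[0, 0, 0] == 2          # outside, fat HU, inferior
        assert labels.data[0, 0, 5] == 0          # outside, fat HU, not inferior

    def test_grid_mismatch_rejected(self, rng):
        vol, _ = self._toy(rng)
        bad = SegmentationMask(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(GridMismatchError):
            make_redundant_class(vol, bad, PreprocessConfig())

    def test_exactly_one_label_per_voxel(self, rng):
        vol, peri = self._toy(rng)
        labels = make_redundant_class(vol, peri, PreprocessConfig())
        assert set(np.unique(labels.data)) <= {0, 1, 2}


class TestPipelineRoundTrip:
    def test_identity_when_already_cube_at_target_spacing(self, rng):
        cfg = PreprocessConfig(target_spacing_mm=1.6, cube_size=32)
        data = rng.uniform(-900, 1300, size=(32, 32, 32)).astype(np.float32)
        vol = CTVolume(data, (1.6, 1.6, 1.6))
        img, _, t = apply_pipeline(vol, None, cfg)
        np.testing.assert_array_equal(img.data, clip_normalize(vol).data)
        assert t.pad_low == t.pad_high == t.crop_low == t.crop_high == (0, 0, 0)

    def test_downsample_without_padding(self, rng):
        cfg = PreprocessConfig(target_spacing_mm=1.6, cube_size=32)
        vol = CTVolume(rng.random((64, 64, 64)), (0.8, 0.8, 0.8))
        img, _, t = apply_pipeline(vol, None, cfg)
        assert t.resampled_shape == (32, 32, 32)
        assert t.pad_low == (0, 0, 0) and t.crop_low == (0, 0, 0)

    def test_all_ones_inverts_to_full_native_grid(self, rng):
        cfg = PreprocessConfig(target_spacing_mm=2.0, cube_size=32)
        vol = CTVolume(rng.random((41, 37, 55)), (1.3, 1.7, 0.9))
        _, _, t = apply_pipeline(vol, None, cfg)
        ones = SegmentationMask(np.ones(t.cube_shape(), dtype=np.uint8), (2.0,) * 3)
        native = invert_to_native(ones, t, vol)
        # un-cropped regions cannot be recovered; everything inside must be 1
        assert native.data.shape == vol.data.shape
        assert native.data.mean() > 0.5

    def test_sphere_survives_forward_inverse_with_high_dice(self, rng):
        cfg = PreprocessConfig(target_spacing_mm=2.0, cube_size=32)
        for _ in range(5):
            shape = (48, 52, 44)
            center = rng.uniform(18, 30, size=3)
            radius = rng.uniform(10, 14)
            idx = np.indices(shape)
            sphere = (
                (idx[0] - center[0]) ** 2 + (idx[1] - center[1]) ** 2
                + (idx[2] - center[2]) ** 2
            ) <= radius ** 2
            vol = CTVolume(rng.random(shape), (1.5, 1.5, 1.5))
            mask = SegmentationMask(sphere.astype(np.uint8), (1.5, 1.5, 1.5))
            res = resample_isotropic(mask, cfg.target_spacing_mm, "nearest")
            cube, t0 = pad_crop_center(res, cfg.cube_size)
            _, _, t = apply_pipeline(vol, None, cfg)
            native = invert_to_native(cube, t, vol)
            assert dice(native, mask) >= 0.9

    def test_labels_share_cube_grid(self, small_phantom):
        vol, truth = small_phantom
        cfg = PreprocessConfig(target_spacing_mm=2.4, cube_size=64)
        img, labels, t = apply_pipeline(vol, truth.pericardium_mask, cfg)
        assert img.data.shape == labels.data.shape == (64, 64, 64)
        assert img.data.min() >= 0.0 and img.data.max() <= 1.0
        assert set(np.unique(labels.data)) <= {0, 1, 2}
        # redundant voxels only in the inferior fifth of the resampled grid
        boundary = math.ceil(0.2 * t.resampled_shape[2]) + t.pad_low[2]
        z_idx = np.nonzero((labels.data == 2).any(axis=(0, 1)))[0]
        assert z_idx.size == 0 or z_idx.max() < boundary

    def test_inverse_shape_mismatch_rejected(self, rng):
        cfg = PreprocessConfig(target_spacing_mm=2.0, cube_size=32)
        vol = CTVolume(rng.random((40, 40, 40)), (1, 1, 1))
        _, _, t = apply_pipeline(vol, None, cfg)
        wrong = SegmentationMask(np.zeros((16, 16, 16), dtype=np.uint8), (2.0,) * 3)
        with pytest.raises(GridMismatchError):
            invert_to_native(wrong, t, vol)
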