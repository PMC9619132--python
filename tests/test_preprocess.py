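import numpy as np
import pytest

import hsiseg
from hsiseg.io import CaptureTriplet, HSICube, LabelMask, default_axis
from hsiseg.phantom import PhantomConfig, generate_phantom
from hsiseg.preprocess import (CalibrationError, PatchSet, ReflectanceCube,
                               augment_flips, compute_foreground_mask,
                               denoise_lowrank, extract_patches,
                               extract_signatures, normalize_reflectance,
                               stitch_patches, zero_background)


def _triplet(it, iw, idark, b=4):
    axis = default_axis(b)
    shape = (3, 3, b)
    return CaptureTriplet(
        target=HSICube(np.full(shape, it), axis, "raw_target"),
        white=HSICube(np.full(shape, iw), axis, "white_reference"),
        dark=HSICube(np.full(shape, idark), axis, "dark_signal"))


def _uniform_cube(h=8, w=8, b=6, value=1.0):
    return ReflectanceCube(np.full((h, w, b), value), default_axis(b),
                           np.ones((h, w), bool))


class TestNormalization:
    def test_flat_field_identity(self):
        """It == Iw with zero dark signal gives unit reflectance."""
        cube = normalize_reflectance(_triplet(1.0, 1.0, 0.0))
        np.testing.assert_allclose(cube.values, 1.0)

    def test_target_equals_dark_gives_zero(self):
        cube = normalize_reflectance(_triplet(0.1, 1.0, 0.1))
        np.testing.assert_allclose(cube.values, 0.0)

    def test_scalar_arithmetic(self):
        cube = normalize_reflectance(_triplet(0.6, 1.0, 0.1))
        np.testing.assert_allclose(cube.values, 0.5 / 0.9)

    def test_degenerate_denominators_zeroed(self):
        t = _triplet(0.5, 1.0, 0.0)
        t.white.values[0, 0, :] = 0.0
        t.dark.values[0, 0, :] = 0.0
        cube = normalize_reflectance(t)
        np.testing.assert_allclose(cube.values[0, 0], 0.0)
        np.testing.assert_allclose(cube.values[1:, :], 0.5)

    def test_all_degenerate_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            normalize_reflectance(_triplet(0.5, 0.2, 0.2))

    def test_clip_negative(self):
        t = _triplet(0.0, 1.0, 0.1)
        assert normalize_reflectance(t, clip_negative=True).values.min() == 0.0
        assert normalize_reflectance(t, clip_negative=False).values.min() < 0.0


class TestDenoise:
    def test_rank_k_input_is_fixed_point(self, rng):
        basis = rng.random((3, 12))
        coeffs = rng.random((64, 3))
        cube = ReflectanceCube((coeffs @ basis).reshape(8, 8, 12),
                               default_axis(12), np.ones((8, 8), bool))
        out = denoise_lowrank(cube, rank=3)
        np.testing.assert_allclose(out.values, cube.values, atol=1e-6)

    def test_projection_is_idempotent(self, rng):
        cube = ReflectanceCube(rng.random((8, 8, 10)), default_axis(10),
                               np.ones((8, 8), bool))
        once = denoise_lowrank(cube, rank=4)
        twice = denoise_lowrank(once, rank=4)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-6)

    def test_residual_monotone_in_rank(self, rng):
        cube = ReflectanceCube(rng.random((8, 8, 10)), default_axis(10),
                               np.ones((8, 8), bool))
        res = []
        for rank in (1, 9):
            out = denoise_lowrank(cube, rank=rank)
            res.append(np.linalg.norm(out.values - cube.values))
        assert res[1] <= res[0]

    def test_zero_iterations_is_identity(self, rng):
        cube = ReflectanceCube(rng.random((6, 6, 8)), default_axis(8),
                               np.ones((6, 6), bool))
        out = denoise_lowrank(cube, rank=2, iterations=0)
        np.testing.assert_array_equal(out.values, cube.values)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            denoise_lowrank(_uniform_cube(), rank=0)
        with pytest.raises(ValueError):
            denoise_lowrank(_uniform_cube(b=6), rank=6)


class TestForegroundMask:
    def test_phantom_mask_matches_true_tissue(self, small_phantom):
        cube = hsiseg.normalize_reflectance(small_phantom.triplet)
        mask = compute_foreground_mask(cube)
        gt = small_phantom.gt_tissue
        iou = np.sum(mask & gt) / np.sum(mask | gt)
        assert iou >= 0.95

    def test_uniform_cube_warns_and_returns_all_ones(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask = compute_foreground_mask(_uniform_cube())
        assert mask.all()

    def test_salt_noise_components_removed(self):
        sample = generate_phantom(PhantomConfig(shape=(64, 64), band_count=12,
                                                noise_sd=0.0, seed=1))
        cube = hsiseg.normalize_reflectance(sample.triplet)
        # inject 3 isolated bright background pixels
        vals = cube.values.copy()
        for r, c in [(2, 2), (2, 60), (60, 2)]:
            assert not sample.gt_tissue[r, c]
            vals[r, c, :] = 0.5
        noisy = ReflectanceCube(vals, cube.axis, cube.foreground)
        mask = compute_foreground_mask(noisy, min_object_px=10)
        for r, c in [(2, 2), (2, 60), (60, 2)]:
            assert not mask[r, c]


class TestZeroBackground:
    def test_identity_mask_unchanged(self, rng):
        cube = ReflectanceCube(rng.random((5, 5, 4)), default_axis(4),
                               np.ones((5, 5), bool))
        out = zero_background(cube, np.ones((5, 5), bool))
        np.testing.assert_array_equal(out.values, cube.values)

    def test_half_mask_zeroes_exactly_half(self, rng):
        cube = ReflectanceCube(rng.random((4, 4, 3)) + 0.1, default_axis(3),
                               np.ones((4, 4), bool))
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        out = zero_background(cube, mask)
        assert np.all(out.values[2:] == 0.0)
        np.testing.assert_array_equal(out.values[:2], cube.values[:2])
        assert out.foreground.sum() == 8


class TestExtractSignatures:
    def test_row_major_order_and_count(self, rng):
        cube = ReflectanceCube(rng.random((3, 3, 5)), default_axis(5),
                               np.ones((3, 3), bool))
        mask = np.zeros((3, 3), bool)
        mask[0, 1] = mask[1, 0] = mask[1, 2] = mask[2, 2] = True
        sig, _ = extract_signatures(cube, mask)
        assert len(sig) == 4
        np.testing.assert_array_equal(sig.pixel_index,
                                      [[0, 1], [1, 0], [1, 2], [2, 2]])
        np.testing.assert_array_equal(sig.rows[0], cube.values[0, 1])

    def test_full_mask_gives_all_pixels(self, rng):
        cube = ReflectanceCube(rng.random((4, 5, 3)), default_axis(3),
                               np.ones((4, 5), bool))
        sig, _ = extract_signatures(cube)
        assert len(sig) == 20

    def test_label_fraction_matches_phantom(self, reflectance_and_gt,
                                            small_phantom):
        cube, gt = reflectance_and_gt
        _, labels = extract_signatures(cube, labels=gt)
        frac = labels.mean()
        assert abs(frac
                   - small_phantom.metadata["tumor_pixel_fraction"]) < 0.02

    def test_empty_mask_rejected(self, rng):
        cube = ReflectanceCube(rng.random((3, 3, 4)), default_axis(4),
                               np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            extract_signatures(cube)


class TestPatches:
    def test_divisible_grid(self, rng):
        cube = ReflectanceCube(rng.random((64, 64, 4)), default_axis(4),
                               np.ones((64, 64), bool))
        ps = extract_patches(cube, patch_size=(32, 32))
        assert len(ps) == 4
        assert sorted(ps.grid_origin) == [(0, 0), (0, 32), (32, 0), (32, 32)]

    def test_drop_empty_keeps_foreground_tile(self, rng):
        cube = ReflectanceCube(rng.random((64, 64, 4)), default_axis(4),
                               np.zeros((64, 64), bool))
        cube.foreground[:32, :32] = True
        ps = extract_patches(cube, drop_empty=True)
        assert len(ps) == 1 and ps.grid_origin[0] == (0, 0)

    def test_mirror_pad_tile_count(self, rng):
        cube = ReflectanceCube(rng.random((70, 70, 3)), default_axis(3),
                               np.ones((70, 70), bool))
        ps = extract_patches(cube, patch_size=(32, 32))
        assert len(ps) == 9                       # ceil(70/32)^2
        assert ps.padded_shape == (96, 96)

    def test_patch_larger_than_cube_rejected(self, rng):
        cube = ReflectanceCube(rng.random((16, 16, 3)), default_axis(3),
                               np.ones((16, 16), bool))
        with pytest.raises(ValueError):
            extract_patches(cube, patch_size=(32, 32))

    def test_dye_filter_drops_patches(self, rng):
        cube = ReflectanceCube(rng.random((64, 64, 4)), default_axis(4),
                               np.ones((64, 64), bool))
        ps = extract_patches(cube, dye_filter=lambda p, fg: p.mean() > -1)
        assert len(ps) == 0


class TestAugmentation:
    def _patchset(self, rng, n=5):
        patches = [rng.random((8, 8, 3)) for _ in range(n)]
        labels = [(rng.random((8, 8)) > 0.5).astype(np.uint8)
                  for _ in range(n)]
        return PatchSet(patches=patches, labels=labels,
                        grid_origin=[(0, 0)] * n, source_shape=(8, 8),
                        patch_size=(8, 8))

    def test_fourfold_count(self, rng):
        ps = self._patchset(rng, 10)
        assert len(augment_flips(ps)) == 40

    def test_double_augmentation_is_sixteenfold(self, rng):
        ps = self._patchset(rng, 3)
        assert len(augment_flips(augment_flips(ps))) == 48

    def test_flips_are_involutions(self, rng):
        ps = augment_flips(self._patchset(rng, 1))
        orig, v, h, vh = ps.patches[:4]
        np.testing.assert_array_equal(v[::-1], orig)
        np.testing.assert_array_equal(h[:, ::-1], orig)
        np.testing.assert_array_equal(vh[::-1, ::-1], orig)

    def test_labels_flip_with_patches(self, rng):
        ps = augment_flips(self._patchset(rng, 2))
        np.testing.assert_array_equal(ps.labels[1][::-1], ps.labels[0])

    def test_constant_patch_has_identical_copies(self):
        ps = PatchSet(patches=[np.ones((4, 4, 2))],
                      labels=[np.zeros((4, 4), np.uint8)],
                      grid_origin=[(0, 0)], source_shape=(4, 4),
                      patch_size=(4, 4))
        out = augment_flips(ps)
        for p in out.patches[1:]:
            np.testing.assert_array_equal(p, out.patches[0])

    def test_only_originals_flagged(self, rng):
        out = augment_flips(self._patchset(rng, 3))
        assert out.originals == [0, 4, 8]


class TestStitching:
    def test_split_then_stitch_is_identity(self, rng):
        for h, w in [(64, 64), (70, 50)]:
            values = rng.random((h, w, 3))
            labels = (rng.random((h, w)) > 0.6).astype(np.uint8)
            cube = ReflectanceCube(values, default_axis(3),
                                   np.ones((h, w), bool))
            ps = extract_patches(cube, LabelMask(labels),
                                 patch_size=(32, 32))
            preds = [p.astype(float) for p in ps.labels]
            out = stitch_patches(preds, ps)
            np.testing.assert_array_equal(out, labels)

    def test_dropped_tile_stays_zero(self, rng):
        cube = ReflectanceCube(rng.random((96, 96, 2)), default_axis(2),
                               np.ones((96, 96), bool))
        cube.foreground[32:64, 32:64] = False
        cube.values[32:64, 32:64] = 0.0
        ps = extract_patches(cube, drop_empty=True)
        assert len(ps) == 8
        out = stitch_patches([np.ones((32, 32))] * 8, ps)
        assert np.all(out[32:64, 32:64] == 0)
        assert np.all(out[:32, :] == 1)

    def test_prediction_count_mismatch_rejected(self, rng):
        cube = ReflectanceCube(rng.random((64, 64, 2)), default_axis(2),
                               np.ones((64, 64), bool))
        ps = extract_patches(cube)
        with pytest.raises(ValueError):
            stitch_patches([np.ones((32, 32))] * 3, ps)

    def test_stitch_ignores_augmented_copies(self, rng):
        cube = ReflectanceCube(rng.random((64, 64, 2)), default_axis(2),
                               np.ones((64, 64), bool))
        ps = augment_flips(extract_patches(cube))
        out = stitch_patches([np.ones((32, 32))] * 4, ps)
        assert out.shape == (64, 64) and np.all(out == 1)
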