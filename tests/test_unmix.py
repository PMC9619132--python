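import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hsiseg
from hsiseg.io import default_axis
from hsiseg.preprocess import ReflectanceCube, zero_background
from hsiseg.unmix import (ClassifierConfig, EndmemberSet, ReferenceLibrary,
                          estimate_abundances, exhaustive_endmembers,
                          fit_pixel_classifier, kmeans_sam_segment,
                          nfindr_endmembers, segment_pixelwise,
                          simplex_volume, spectral_angle,
                          subsample_equal_interval, tune_pixel_classifier,
                          _project)


class TestSpectralAngle:
    def test_identical_vectors(self):
        assert spectral_angle([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_orthogonal_vectors(self):
        assert spectral_angle([1, 0], [0, 1]) == pytest.approx(np.pi / 2)

    def test_hand_case_45_degrees(self):
        assert spectral_angle([1, 1], [1, 0]) == pytest.approx(np.pi / 4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([0, 0], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(10) + 0.01
        y = rng.random(10) + 0.01
        assert spectral_angle(scale * x, y) == pytest.approx(
            spectral_angle(x, y), abs=1e-9)


class TestNFindr:
    def test_recovers_simplex_vertices_from_mixtures(self, rng):
        """Strict interior mixtures can never enlarge the vertex simplex."""
        k = 4
        vertices = rng.random((k, 16)) + np.eye(k, 16) * 2.0
        weights = rng.dirichlet(np.ones(k) * 2.0, size=500)
        # keep mixtures strictly interior
        weights = 0.9 * weights + 0.1 / k
        data = np.vstack([vertices, weights @ vertices])
        em = nfindr_endmembers(data, k=k, seed=0)
        got = {tuple(np.round(row, 9)) for row in em.spectra}
        expected = {tuple(np.round(row, 9)) for row in vertices}
        assert got == expected

    def test_k2_returns_extremes(self, rng):
        data = np.outer(np.linspace(0.1, 1.0, 20), np.ones(5))
        data += rng.normal(0, 1e-3, data.shape)
        em = nfindr_endmembers(data, k=2, seed=1)
        idx, _ = exhaustive_endmembers(data, 2)
        got = {tuple(r) for r in em.spectra}
        assert got == {tuple(data[i]) for i in idx}

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_exhaustive_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        data = rng.random((12, 6))
        em = nfindr_endmembers(data, k=k, seed=seed)
        _, best_vol = exhaustive_endmembers(data, k)
        proj = _project(data, k)
        rows = [np.flatnonzero((data == e).all(axis=1))[0]
                for e in em.spectra]
        assert simplex_volume(proj[rows]) == pytest.approx(best_vol,
                                                           rel=1e-9)

    def test_rank_deficient_data_rejected(self):
        data = np.outer(np.arange(10), np.ones(6))   # rank 1 after centering
        with pytest.raises(ValueError):
            nfindr_endmembers(data, k=4, seed=0)


@pytest.fixture(scope="module")
def endmembers():
    rng = np.random.default_rng(42)
    return EndmemberSet(rng.random((4, 20)) + 0.1 * np.eye(4, 20))


class TestAbundances:

    def test_pure_signature_is_one_hot(self, endmembers):
        am = estimate_abundances(endmembers.spectra[2:3], endmembers)
        np.testing.assert_allclose(am.values[0], [0, 0, 1, 0], atol=1e-9)

    def test_noiseless_mixture_recovered(self, endmembers):
        s = 0.3 * endmembers.spectra[0] + 0.7 * endmembers.spectra[1]
        am = estimate_abundances(s[None], endmembers)
        np.testing.assert_allclose(am.values[0], [0.3, 0.7, 0, 0], atol=1e-6)

    def test_fcls_rows_sum_to_one_and_nonnegative(self, endmembers, rng):
        data = rng.random((50, 20))
        am = estimate_abundances(data, endmembers, mode="fcls")
        np.testing.assert_allclose(am.values.sum(axis=1), 1.0, atol=1e-6)
        assert am.values.min() >= -1e-9

    def test_nnls_nonnegative_only(self, endmembers, rng):
        data = rng.random((20, 20))
        am = estimate_abundances(data, endmembers, mode="nnls")
        assert am.values.min() >= 0.0

    def test_ols_exact_on_noiseless(self, endmembers):
        coeffs = np.array([[0.2, -0.1, 0.5, 0.4]])
        s = coeffs @ endmembers.spectra
        am = estimate_abundances(s, endmembers, mode="ols")
        np.testing.assert_allclose(am.values, coeffs, atol=1e-8)

    def test_too_many_endmembers_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_abundances(rng.random((5, 3)),
                                EndmemberSet(rng.random((4, 3))))


def _matched_reference_library(sample, rng, noise=0.01):
    normal = sample.metadata["normal_mean_spectrum"]
    tumor = sample.metadata["tumor_mean_spectrum"]
    b = len(normal)
    spectra = np.vstack(
        [[normal * (1 + noise * rng.standard_normal(b)) for _ in range(3)],
         [tumor * (1 + noise * rng.standard_normal(b)) for _ in range(3)]])
    return ReferenceLibrary(spectra=spectra,
                            class_of=["normal"] * 3 + ["tumor"] * 3)


class TestKmeansSam:
    def test_matched_references_give_high_jc(self, small_phantom,
                                             reflectance_and_gt, rng):
        cube, gt = reflectance_and_gt
        refs = _matched_reference_library(small_phantom, rng)
        result = kmeans_sam_segment(cube, refs, seed=0)
        report = hsiseg.evalkit.evaluate_segmentation(result, gt)
        assert report.jc >= 90.0

    def test_background_never_tumor(self, small_phantom, reflectance_and_gt,
                                    rng):
        cube, _ = reflectance_and_gt
        refs = _matched_reference_library(small_phantom, rng)
        result = kmeans_sam_segment(cube, refs, seed=0)
        assert not result.mask[~cube.foreground].any()

    def test_identical_references_tie_to_non_tumor(self, reflectance_and_gt,
                                                   rng):
        cube, _ = reflectance_and_gt
        spec = rng.random((1, cube.axis.band_count)) + 0.5
        refs = ReferenceLibrary(spectra=np.vstack([spec, spec]),
                                class_of=["normal", "tumor"])
        with pytest.warns(UserWarning, match="identical"):
            result = kmeans_sam_segment(cube, refs, seed=0)
        assert result.mask.sum() == 0

    def test_single_cluster_assigns_nearest_class(self, small_phantom,
                                                  reflectance_and_gt, rng):
        cube, _ = reflectance_and_gt
        refs = _matched_reference_library(small_phantom, rng)
        result = kmeans_sam_segment(cube, refs, n_clusters=1, seed=0)
        labels = result.mask[cube.foreground]
        assert len(np.unique(labels)) == 1


class TestSubsampling:
    def test_ten_percent_stride(self):
        rows = np.arange(1000)[:, None]
        sub, _ = subsample_equal_interval(rows, fraction=0.10)
        np.testing.assert_array_equal(sub.ravel(), np.arange(0, 1000, 10))

    def test_full_fraction_is_identity(self, rng):
        rows = rng.random((13, 4))
        sub, _ = subsample_equal_interval(rows, fraction=1.0)
        np.testing.assert_array_equal(sub, rows)

    def test_stride_arithmetic_on_seven_rows(self):
        rows = np.arange(7)[:, None]
        sub, labels = subsample_equal_interval(rows, np.arange(7),
                                               fraction=0.5)
        np.testing.assert_array_equal(sub.ravel(), [0, 2, 4, 6])
        np.testing.assert_array_equal(labels, [0, 2, 4, 6])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            subsample_equal_interval(np.arange(4)[:, None], fraction=0.0)


class TestPixelClassifier:
    def _blobs(self, rng, n=200, margin=2.0):
        x = np.vstack([rng.normal(0, 1, (n // 2, 2)),
                       rng.normal(2 * margin, 1, (n // 2, 2))])
        y = np.repeat([0, 1], n // 2)
        return x, y

    def test_separable_blobs_high_accuracy(self, rng):
        x, y = self._blobs(rng)
        model = fit_pixel_classifier(x, y)
        assert (model.predict(x) == y).mean() >= 0.99

    def test_consistent_duplicates_reproduced(self):
        x = np.repeat([[0.0, 0.0], [1.0, 1.0]], 10, axis=0)
        y = np.repeat([0, 1], 10)
        model = fit_pixel_classifier(x, y)
        np.testing.assert_array_equal(model.predict(x), y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pixel_classifier(rng.random((10, 3)), np.zeros(10))

    def test_default_config_matches_observed_optimum(self):
        cfg = ClassifierConfig()
        assert cfg.kernel == "rbf"
        assert cfg.box_constraint == pytest.approx(44.184)
        assert cfg.kernel_scale == pytest.approx(4.0136)

    def test_tuning_deterministic_and_non_regressing(self, rng):
        x, y = self._blobs(rng, n=80, margin=1.0)
        a = tune_pixel_classifier(x, y, budget=5, seed=3)
        b = tune_pixel_classifier(x, y, budget=5, seed=3)
        assert a == b
        assert a["search"] == "random"
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC
        default = ClassifierConfig()
        base = np.mean(cross_val_score(
            SVC(C=default.box_constraint, kernel="rbf",
                gamma=default.gamma), x, y, cv=3))
        assert a["cv_accuracy"] >= base - 1e-12

    def test_budget_one_returns_a_config(self, rng):
        x, y = self._blobs(rng, n=40)
        out = tune_pixel_classifier(x, y, budget=1, seed=0)
        assert out["kernel"] in ("linear", "rbf")


class TestSegmentPixelwise:
    def test_phantom_family_generalization(self, rng):
        """Train on one phantom, segment another from the same family."""
        samples = hsiseg.generate_dataset(
            2, seed=21,
            base_config=hsiseg.PhantomConfig(shape=(64, 64), band_count=30))
        cubes = []
        for s in samples:
            c = hsiseg.normalize_reflectance(s.triplet)
            cubes.append(zero_background(c, s.gt_tissue))
        sig, y = hsiseg.extract_signatures(cubes[0],
                                           labels=samples[0].gt_tumor)
        sub_x, sub_y = subsample_equal_interval(sig.rows, y, 0.10)
        model = fit_pixel_classifier(sub_x, sub_y)
        result = segment_pixelwise(cubes[1], model)
        report = hsiseg.evalkit.evaluate_segmentation(
            result, samples[1].gt_tumor)
        assert report.jc >= 70.0
        assert result.mask.shape == cubes[1].shape[:2]

    def test_all_background_cube_gives_zero_mask(self, rng):
        cube = ReflectanceCube(rng.random((8, 8, 5)), default_axis(5),
                               np.zeros((8, 8), bool))
        x = np.vstack([rng.random((10, 5)), rng.random((10, 5)) + 1])
        model = fit_pixel_classifier(x, np.repeat([0, 1], 10))
        result = segment_pixelwise(cube, model)
        assert result.mask.sum() == 0

    def test_band_mismatch_rejected(self, rng):
        cube = ReflectanceCube(rng.random((8, 8, 5)), default_axis(5),
                               np.ones((8, 8), bool))
        x = np.vstack([rng.random((10, 7)), rng.random((10, 7)) + 1])
        model = fit_pixel_classifier(x, np.repeat([0, 1], 10))
        with pytest.raises(ValueError):
            segment_pixelwise(cube, model)

    def test_abundance_mode_requires_endmembers(self, rng):
        cube = ReflectanceCube(rng.random((8, 8, 5)), default_axis(5),
                               np.ones((8, 8), bool))
        x = np.vstack([rng.random((10, 3)), rng.random((10, 3)) + 1])
        model = fit_pixel_classifier(x, np.repeat([0, 1], 10),
                                     feature_mode="abundance")
        with pytest.raises(ValueError):
            segment_pixelwise(cube, model)
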