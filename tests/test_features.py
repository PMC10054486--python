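"""Engineered predictors: PC1, GLCM textures, wavelet details, indices."""

import numpy as np
import pytest
import pywt

from agbmap.features import (DEFAULT_INDEX_REGISTRY, GLCM_FEATURE_NAMES,
                             first_principal_component, glcm_features,
                             spectral_indices, wavelet_textures)
from agbmap.geodata import MultispectralScene

from glcm_oracle import full_plane_stats

F = {name: i for i, name in enumerate(GLCM_FEATURE_NAMES)}


def _scene(values, mask=None):
    return MultispectralScene(
        values=values,
        band_labels=tuple(f"b{i}" for i in range(values.shape[2])),
        pixel_size=100.0, origin=(0.0, 0.0), nodata_mask=mask)


class TestPC1:
    def test_single_band_equals_centered_band(self, rng):
        vals = rng.random((8, 8, 1))
        pc1 = first_principal_component(_scene(vals))
        centered = vals[:, :, 0] - vals[:, :, 0].mean()
        # equal up to sign; the sign convention fixes loading >= 0
        np.testing.assert_allclose(pc1, centered, atol=1e-12)

    def test_two_identical_bands_explain_all_variance(self, rng):
        b = rng.random((8, 8))
        vals = np.stack([b, b], axis=2)
        pc1 = first_principal_component(_scene(vals))
        # oracle: 2×2 covariance [[v,v],[v,v]] has eigvec (1,1)/√2
        expected = (b - b.mean()) * np.sqrt(2.0)
        np.testing.assert_allclose(pc1, expected, atol=1e-10)
        assert pc1.var() >= vals[:, :, 0].var() - 1e-12

    def test_constant_band_gets_zero_loading(self):
        checker = np.indices((8, 8)).sum(axis=0) % 2 * 1.0
        vals = np.stack([checker, np.full((8, 8), 0.3)], axis=2)
        pc1 = first_principal_component(_scene(vals))
        np.testing.assert_allclose(pc1, checker - checker.mean(), atol=1e-12)

    def test_all_constant_scene_rejected(self):
        with pytest.raises(ValueError):
            first_principal_component(_scene(np.full((4, 4, 2), 0.5)))

    def test_pc1_variance_dominates_each_band(self, rng):
        vals = rng.random((16, 16, 5))
        pc1 = first_principal_component(_scene(vals))
        for b in range(5):
            assert pc1.var() >= vals[:, :, b].var() - 1e-10


class TestGLCM:
    def test_constant_window_conventions(self):
        out = glcm_features(np.full((7, 7), 3.0), window=5).planes
        center = out[3, 3]
        assert center[F["glcm_contrast"]] == 0
        assert center[F["glcm_dissimilarity"]] == 0
        assert center[F["glcm_homogeneity"]] == pytest.approx(1.0)
        assert center[F["glcm_second_moment"]] == pytest.approx(1.0)
        assert center[F["glcm_entropy"]] == pytest.approx(0.0, abs=1e-12)
        assert center[F["glcm_correlation"]] == 0.0   # degenerate marginal

    def test_checkerboard_contrast_and_homogeneity(self):
        # two-level checkerboard: every distance-1 horizontal/vertical pair
        # jumps the full quantization gap g -> contrast g², homog 1/(1+g²)
        levels = 8
        checker = np.indices((9, 9)).sum(axis=0) % 2 * 1.0
        out = glcm_features(checker, window=5, levels=levels).planes
        g = levels - 1
        center = out[4, 4]
        # horizontal offset alone gives exactly g²; diagonals give 0.
        # offset-averaged: (g² + 0 + g² + 0) / 2... verified by oracle below;
        # here check the horizontal-only prediction via the oracle structure
        expected = full_plane_stats(checker, 5, levels)[4, 4]
        np.testing.assert_allclose(center, expected, atol=1e-9)
        assert expected[F["glcm_contrast"]] == pytest.approx(g * g / 2)
        assert expected[F["glcm_homogeneity"]] == pytest.approx(
            (1.0 / (1 + g * g) + 1.0) / 2)

    def test_matches_bruteforce_on_random_patches(self, rng):
        for _ in range(6):
            patch = rng.integers(0, 8, size=(7, 7)).astype(float)
            got = glcm_features(patch, window=5, levels=8).planes
            want = full_plane_stats(patch, 5, 8)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_agrees_with_skimage_cooccurrence(self, rng):
        """Cross-check against an established co-occurrence implementation:
        a 5×5 window's feature vector equals the statistics of
        skimage.feature.graycomatrix (symmetric, normed, 4 directions)."""
        from skimage.feature import graycomatrix
        patch = rng.integers(0, 8, size=(5, 5)).astype(np.uint8)
        patch[0, 0], patch[4, 4] = 0, 7     # pin the quantization range
        got = glcm_features(patch.astype(float), window=5, levels=8) \
            .planes[2, 2]
        P = graycomatrix(patch, [1], [0, np.pi / 4, np.pi / 2,
                                      3 * np.pi / 4],
                         levels=8, symmetric=True, normed=True)
        i, j = np.indices((8, 8))
        stats = []
        for a in range(4):
            p = P[:, :, 0, a]
            mu = (i * p).sum()
            var = (((i - mu) ** 2) * p).sum()
            nz = p > 0
            corr = ((((i - mu) * (j - mu) * p).sum() / var)
                    if var > 1e-12 else 0.0)
            stats.append([
                mu, var, (p / (1 + (i - j) ** 2)).sum(),
                (((i - j) ** 2) * p).sum(), (np.abs(i - j) * p).sum(),
                -(p[nz] * np.log(p[nz])).sum(), (p ** 2).sum(), corr])
        np.testing.assert_allclose(got, np.mean(stats, axis=0), atol=1e-9)

    def test_feature_ranges(self, rng):
        plane = rng.random((12, 12))
        out = glcm_features(plane, window=5).planes
        assert (out[:, :, F["glcm_homogeneity"]] > 0).all()
        assert (out[:, :, F["glcm_homogeneity"]] <= 1 + 1e-12).all()
        assert (out[:, :, F["glcm_second_moment"]] > 0).all()
        assert (out[:, :, F["glcm_second_moment"]] <= 1 + 1e-12).all()
        assert (out[:, :, F["glcm_entropy"]] >= 0).all()
        assert (out[:, :, F["glcm_contrast"]] >= 0).all()

    def test_window_validation(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((8, 8)), window=4)
        with pytest.raises(ValueError):
            glcm_features(np.zeros((8, 8)), window=5, levels=1)

    def test_footprint_at_training_resolution(self):
        # 5 pixels at the 100 m training grid span 500 m per side
        assert 5 * 100.0 == 500.0


class TestWaveletTextures:
    def test_three_levels_give_nine_planes(self, rng):
        out = wavelet_textures(rng.random((32, 32)), levels=3)
        assert out.n_features == 9
        for lev in (1, 2, 3):
            for orient in ("horizontal", "vertical", "diagonal"):
                assert f"wav_L{lev}_{orient}" in out.names

    def test_one_level_gives_three_planes(self, rng):
        assert wavelet_textures(rng.random((16, 16)), levels=1).n_features == 3

    def test_constant_plane_has_zero_detail(self):
        out = wavelet_textures(np.full((32, 32), 7.0), levels=3)
        np.testing.assert_allclose(out.planes, 0.0, atol=1e-10)

    def test_too_small_plane_rejected(self):
        with pytest.raises(ValueError):
            wavelet_textures(np.zeros((4, 4)), levels=3)

    def test_level1_reconstruction(self, rng):
        # approximation + details invert to the source plane
        plane = rng.random((32, 32))
        cA, details = pywt.wavedec2(plane, "coif1", mode="symmetric",
                                    level=1)
        back = pywt.waverec2([cA, details], "coif1", mode="symmetric")
        np.testing.assert_allclose(back[:32, :32], plane, atol=1e-8)

    def test_planes_aligned_with_source_grid(self, rng):
        out = wavelet_textures(rng.random((40, 24)), levels=3)
        assert out.planes.shape[:2] == (40, 24)


class TestSpectralIndices:
    def _scene(self, nir, red):
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = [red, nir]
        return MultispectralScene(values=vals, band_labels=("B04", "B08"),
                                  pixel_size=100.0, origin=(0, 0))

    @pytest.mark.parametrize("nir,red,expected", [
        (0.5, 0.1, 0.4 / 0.6),     # direct evaluation of the NDVI ratio
        (0.3, 0.3, 0.0),           # symmetric
        (0.0, 0.0, 0.0),           # divide-by-zero convention
    ])
    def test_ndvi(self, nir, red, expected):
        reg = {"ndvi": "(B08 - B04) / (B08 + B04)"}
        out = spectral_indices(self._scene(nir, red), reg)
        assert out.planes[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_divzero_flagged_in_provenance(self):
        reg = {"ndvi": "(B08 - B04) / (B08 + B04)"}
        out = spectral_indices(self._scene(0.0, 0.0), reg)
        assert out.provenance[0]["divzero_count"] == 1

    def test_missing_band_named_in_error(self):
        with pytest.raises(KeyError, match="ndmi.*B11|B11.*ndmi"):
            spectral_indices(self._scene(0.5, 0.1),
                             {"ndmi": "(B08 - B11) / (B08 + B11)"})

    def test_default_registry_covers_eleven_indices(self, clean_pair):
        scene, _, _ = clean_pair
        out = spectral_indices(scene)
        assert out.n_features == len(DEFAULT_INDEX_REGISTRY) == 11
        assert np.isfinite(out.planes).all()
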