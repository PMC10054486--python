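"""Raster container semantics: reflectance scaling, band selection,
resampling, WKT clipping and TIFF round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agbmap.geodata import (AGBRaster, AlignmentError, DataIntegrityError,
                            MultispectralScene, SENTINEL2_BANDS,
                            check_aligned, clip_to_wkt, dn_to_reflectance,
                            read_agb, read_scene, resample, select_bands,
                            write_raster)


def _scene(values, pixel_size=100.0, origin=(0.0, 0.0), mask=None):
    labels = tuple(f"band_{i}" for i in range(values.shape[2]))
    return MultispectralScene(values=values, band_labels=labels,
                              pixel_size=pixel_size, origin=origin,
                              nodata_mask=mask)


class TestDnToReflectance:
    @pytest.mark.parametrize("dn,expected", [
        (10_000, 1.0),        # the product's quantification value itself
        (0, 0.0),
        (4_532, 0.4532),
    ])
    def test_division_rule(self, dn, expected):
        scene = dn_to_reflectance(np.full((2, 2, 3), dn, dtype=np.int64))
        assert scene.values[0, 0, 0] == pytest.approx(expected, abs=0)

    def test_negative_dn_rejected(self):
        dn = np.zeros((2, 2, 3), dtype=np.int64)
        dn[0, 0, 1] = -5
        with pytest.raises(DataIntegrityError):
            dn_to_reflectance(dn)

    def test_negative_dn_under_nodata_tolerated(self):
        dn = np.zeros((2, 2, 3), dtype=np.int64)
        dn[0, 0, :] = -1
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        scene = dn_to_reflectance(dn, nodata_mask=mask)
        assert scene.nodata_mask[0, 0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=65535),
           st.integers(min_value=1, max_value=20000))
    def test_roundtrip_with_quantification(self, dn, q):
        scene = dn_to_reflectance(np.full((1, 1, 1), dn, np.int64), q)
        assert scene.values[0, 0, 0] * q == pytest.approx(dn, rel=1e-12)


class TestSelectBands:
    def test_default_thirteen_to_ten(self):
        vals = np.random.default_rng(0).random((4, 4, 13))
        scene = MultispectralScene(values=vals, band_labels=SENTINEL2_BANDS,
                                   pixel_size=10.0, origin=(0, 0))
        out = select_bands(scene)
        assert out.n_bands == 10
        for b in ("B01", "B09", "B10"):
            assert b not in out.band_labels
        # order of the retained bands is preserved
        kept = [b for b in SENTINEL2_BANDS if b not in ("B01", "B09", "B10")]
        assert out.band_labels == tuple(kept)

    def test_empty_drop_is_identity(self):
        scene = _scene(np.random.default_rng(1).random((3, 3, 4)))
        out = select_bands(scene, drop=())
        assert out.band_labels == scene.band_labels
        np.testing.assert_array_equal(out.values, scene.values)

    def test_duplicate_label_rejected(self):
        scene = _scene(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            select_bands(scene, drop=("band_0", "band_0"))

    def test_unknown_label_named_in_error(self):
        scene = _scene(np.zeros((2, 2, 3)))
        with pytest.raises(KeyError, match="B99"):
            select_bands(scene, drop=("B99",))


class TestResample:
    def test_block_mean_matches_explicit_averaging(self, rng):
        vals = rng.random((160, 160, 2))
        scene = _scene(vals, pixel_size=10.0)
        out = resample(scene, 100.0, "block_mean")
        assert out.shape == (16, 16)
        # oracle: explicit 10×10 block loop
        for i, j in [(0, 0), (3, 7), (15, 15)]:
            block = vals[i * 10:(i + 1) * 10, j * 10:(j + 1) * 10]
            np.testing.assert_allclose(out.values[i, j],
                                       block.mean(axis=(0, 1)), rtol=1e-12)

    def test_block_mean_ignores_invalid_pixels(self):
        vals = np.ones((4, 4, 1))
        mask = np.zeros((4, 4), bool)
        vals[0, 0, 0] = 1000.0
        mask[0, 0] = True
        scene = _scene(vals, pixel_size=10.0, mask=mask)
        out = resample(scene, 20.0, "block_mean")
        assert out.values[0, 0, 0] == pytest.approx(1.0)

    def test_all_nodata_block_is_nodata(self):
        vals = np.ones((4, 4, 1))
        mask = np.zeros((4, 4), bool)
        mask[:2, :2] = True
        out = resample(_scene(vals, 10.0, mask=mask), 20.0, "block_mean")
        assert out.nodata_mask[0, 0] and not out.nodata_mask[0, 1]

    def test_identity_resolution(self):
        scene = _scene(np.random.default_rng(3).random((8, 8, 1)), 10.0)
        out = resample(scene, 10.0)
        np.testing.assert_array_equal(out.values, scene.values)

    def test_bilinear_upscale_10x(self):
        agb = AGBRaster(values=np.random.default_rng(4).random((16, 16)),
                        pixel_size=100.0, origin=(0, 0))
        out = resample(agb, 10.0, "bilinear")
        assert out.shape == (160, 160)

    def test_non_integer_block_ratio_rejected(self):
        scene = _scene(np.zeros((9, 9, 1)), 10.0)
        with pytest.raises(ValueError):
            resample(scene, 25.0, "block_mean")

    def test_block_mean_conserves_spatial_mean(self, rng):
        vals = rng.random((40, 40, 1))
        out = resample(_scene(vals, 10.0), 40.0, "block_mean")
        assert out.values.mean() == pytest.approx(vals.mean(), rel=1e-12)


class TestClipToWkt:
    def _grid(self, h=16, w=16):
        vals = np.arange(h * w, dtype=float).reshape(h, w, 1)
        return _scene(vals, pixel_size=1.0, origin=(0.0, float(h)))

    def test_full_extent_is_identity(self):
        scene = self._grid()
        wkt = "POLYGON ((0 0, 16 0, 16 16, 0 16, 0 0))"
        out = clip_to_wkt(scene, wkt)
        assert out.shape == scene.shape
        np.testing.assert_array_equal(out.values, scene.values)

    def test_left_half_window(self):
        scene = self._grid()
        wkt = "POLYGON ((0 0, 8 0, 8 16, 0 16, 0 0))"
        out = clip_to_wkt(scene, wkt)
        assert out.shape == (16, 8)
        # oracle: pixel-center point-in-polygon — all centers x<8 inside
        assert not out.nodata_mask.any()
        np.testing.assert_array_equal(out.values, scene.values[:, :8])

    def test_clip_is_idempotent(self):
        scene = self._grid()
        wkt = "POLYGON ((1.2 2.3, 11 2.3, 11 13.7, 1.2 13.7, 1.2 2.3))"
        once = clip_to_wkt(scene, wkt)
        twice = clip_to_wkt(once, wkt)
        assert once.shape == twice.shape
        np.testing.assert_array_equal(once.nodata_mask, twice.nodata_mask)
        np.testing.assert_array_equal(
            once.values[~once.nodata_mask], twice.values[~twice.nodata_mask])

    def test_disjoint_polygon_rejected(self):
        scene = self._grid()
        with pytest.raises(ValueError):
            clip_to_wkt(scene,
                        "POLYGON ((100 100, 110 100, 110 110, 100 100))")

    def test_garbage_wkt_rejected(self):
        with pytest.raises(ValueError):
            clip_to_wkt(self._grid(), "POLYGON ((not wkt")


class TestAlignment:
    def test_misaligned_origin_rejected(self, small_pair):
        scene, agb, _ = small_pair
        shifted = AGBRaster(values=agb.values, pixel_size=agb.pixel_size,
                            origin=(agb.origin[0] + 75.0, agb.origin[1]),
                            nodata_mask=agb.nodata_mask)
        with pytest.raises(AlignmentError):
            check_aligned(scene, shifted)

    def test_aligned_pair_passes(self, small_pair):
        scene, agb, _ = small_pair
        check_aligned(scene, agb)


class TestRasterIO:
    def test_scene_roundtrip(self, tmp_path, small_pair):
        scene, _, _ = small_pair
        path = tmp_path / "scene.tif"
        write_raster(path, scene)
        back = read_scene(path)
        assert back.band_labels == scene.band_labels
        assert back.pixel_size == scene.pixel_size
        assert back.origin == scene.origin
        assert back.acquisition_date == scene.acquisition_date
        np.testing.assert_allclose(back.values[~back.nodata_mask],
                                   scene.values[~scene.nodata_mask],
                                   rtol=1e-6)
        np.testing.assert_array_equal(back.nodata_mask, scene.nodata_mask)

    def test_agb_roundtrip(self, tmp_path, small_pair):
        _, agb, _ = small_pair
        path = tmp_path / "agb.tif"
        write_raster(path, agb)
        back = read_agb(path)
        assert back.pixel_size == agb.pixel_size
        np.testing.assert_array_equal(back.nodata_mask, agb.nodata_mask)
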