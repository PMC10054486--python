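"""Georeferenced raster containers and grid operations.

The two container types — :class:`MultispectralScene` for reflectance cubes
and :class:`AGBRaster` for above-ground biomass surfaces — share a simple
georeferencing model: square pixels, origin at the map coordinate of the
top-left pixel *corner*, rows increasing southward (decreasing y), 0-based
row-major pixel indices, half-open windows.

Rasters are read and written as TIFF files; the georeferencing, band labels
and nodata convention travel in a JSON document stored in the TIFF
``ImageDescription`` tag, and invalid pixels are stored as NaN.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
import tifffile
from scipy import ndimage

__all__ = [
    "DataIntegrityError",
    "AlignmentError",
    "MultispectralScene",
    "AGBRaster",
    "SENTINEL2_BANDS",
    "DEFAULT_DROP_BANDS",
    "dn_to_reflectance",
    "select_bands",
    "resample",
    "clip_to_wkt",
    "check_aligned",
    "read_scene",
    "read_agb",
    "write_raster",
]

#: The 13 spectral channels of the Sentinel-2 multispectral instrument.
SENTINEL2_BANDS = (
    "B01", "B02", "B03", "B04", "B05", "B06", "B07",
    "B08", "B8A", "B09", "B10", "B11", "B12",
)

#: Coarse 60 m channels excluded from the model input (13 -> 10 bands).
DEFAULT_DROP_BANDS = ("B01", "B09", "B10")


class DataIntegrityError(ValueError):
    """Raised when raster contents violate a physical precondition."""


class AlignmentError(ValueError):
    """Raised when two rasters expected on the same grid are not."""


@dataclass
class MultispectralScene:
    """A co-registered stack of reflectance bands.

    ``values`` is H×W×B, dimensionless reflectance (nominally in [0, 1],
    values above 1 are permitted — bright surfaces do occur). ``nodata_mask``
    is True where a pixel is invalid in *any* band.
    """

    values: np.ndarray
    band_labels: tuple
    pixel_size: float
    origin: tuple
    crs_id: str = "local"
    acquisition_date: _dt.date | None = None
    nodata_mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("scene values must be H×W×B")
        self.band_labels = tuple(self.band_labels)
        if len(self.band_labels) != self.values.shape[2]:
            raise ValueError(
                f"{len(self.band_labels)} band labels for "
                f"{self.values.shape[2]} bands"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values).all(axis=2)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[:2]:
            raise ValueError("nodata_mask shape mismatch")
        bad = ~np.isfinite(self.values).all(axis=2) & ~self.nodata_mask
        if bad.any():
            raise DataIntegrityError("non-finite values outside nodata mask")

    @property
    def shape(self):
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band(self, label: str) -> np.ndarray:
        """Return one band plane by label."""
        try:
            idx = self.band_labels.index(label)
        except ValueError:
            raise KeyError(f"band {label!r} not present in scene") from None
        return self.values[:, :, idx]


@dataclass
class AGBRaster:
    """Above-ground biomass density surface in Mg/ha (= t/ha).

    ``kind`` distinguishes observed products (non-negative by physics,
    enforced) from model predictions, whose linear output head may produce
    negative values that are clamped only when carbon stocks are reported.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple
    crs_id: str = "local"
    nodata_mask: np.ndarray = None
    kind: str = "observed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("AGB values must be H×W")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape mismatch")
        valid = ~self.nodata_mask
        vals = self.values[valid]
        if not np.isfinite(vals).all():
            raise DataIntegrityError("non-finite AGB outside nodata mask")
        if self.kind == "observed" and (vals < 0).any():
            raise DataIntegrityError("negative AGB density")

    @property
    def shape(self):
        return self.values.shape


def dn_to_reflectance(
    raster_dn: np.ndarray,
    quantification: int = 10000,
    *,
    band_labels=None,
    pixel_size: float = 10.0,
    origin=(0.0, 0.0),
    crs_id: str = "local",
    acquisition_date=None,
    nodata_mask=None,
) -> MultispectralScene:
    """Convert raw digital numbers to reflectance.

    Level-2A products store quantized digital numbers; reflectance is
    recovered by dividing by the product's quantification value (10,000).
    """
    if quantification <= 0:
        raise ValueError("quantification must be a positive integer")
    dn = np.asarray(raster_dn)
    if dn.ndim != 3:
        raise ValueError("raster_dn must be H×W×B")
    if nodata_mask is None:
        nodata_mask = np.zeros(dn.shape[:2], dtype=bool)
    nodata_mask = np.asarray(nodata_mask, dtype=bool)
    valid = ~nodata_mask
    if (dn[valid] < 0).any():
        raise DataIntegrityError("negative digital numbers in valid pixels")
    values = dn.astype(np.float64) / float(quantification)
    values[nodata_mask] = np.nan
    if band_labels is None:
        if dn.shape[2] == 13:
            band_labels = SENTINEL2_BANDS
        else:
            band_labels = tuple(f"band_{i}" for i in range(dn.shape[2]))
    return MultispectralScene(
        values=values,
        band_labels=band_labels,
        pixel_size=pixel_size,
        origin=tuple(origin),
        crs_id=crs_id,
        acquisition_date=acquisition_date,
        nodata_mask=nodata_mask,
    )


def select_bands(scene: MultispectralScene, drop=DEFAULT_DROP_BANDS) -> MultispectralScene:
    """Drop bands by label, preserving the order of the retained ones.

    The default removes the three 60 m atmospheric channels, turning a
    13-band scene into the 10-band model input.
    """
    drop = tuple(drop)
    if len(set(drop)) != len(drop):
        raise ValueError("drop list contains a duplicated label")
    for label in drop:
        if label not in scene.band_labels:
            raise KeyError(f"band {label!r} not present in scene")
    keep = [i for i, b in enumerate(scene.band_labels) if b not in drop]
    return replace(
        scene,
        values=scene.values[:, :, keep],
        band_labels=tuple(scene.band_labels[i] for i in keep),
        nodata_mask=scene.nodata_mask.copy(),
    )


def _raster_planes(raster):
    """View any raster as H×W×K plus a reconstruction hint."""
    if isinstance(raster, MultispectralScene):
        return raster.values, raster.nodata_mask
    return raster.values[:, :, None], raster.nodata_mask


def _rebuild(raster, values, mask, pixel_size, origin):
    if isinstance(raster, MultispectralScene):
        return replace(raster, values=values, nodata_mask=mask,
                       pixel_size=pixel_size, origin=origin)
    return replace(raster, values=values[:, :, 0], nodata_mask=mask,
                   pixel_size=pixel_size, origin=origin)


def _fill_nearest(plane: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid neighbour's value."""
    if not mask.any():
        return plane
    if mask.all():
        return np.zeros_like(plane)
    idx = ndimage.distance_transform_edt(mask, return_distances=False,
                                         return_indices=True)
    return plane[tuple(idx)]


def resample(raster, target_pixel_size: float, method: str = "block_mean"):
    """Resample a raster to a new grid resolution.

    ``block_mean`` aggregates integer-ratio downsampling (e.g. 10 m native
    bands to the 100 m biomass grid), averaging only valid pixels; a block
    with no valid pixel becomes nodata. ``nearest`` and ``bilinear`` support
    arbitrary ratios (e.g. upscaling a trained grid to 10 m for inference);
    they fill nodata with nearest-valid values before interpolating and
    propagate the mask by nearest-neighbour lookup.
    """
    if target_pixel_size <= 0:
        raise ValueError("target_pixel_size must be positive")
    values, mask = _raster_planes(raster)
    src = raster.pixel_size
    if math.isclose(target_pixel_size, src):
        return _rebuild(raster, values.copy(), mask.copy(), src, raster.origin)
    H, W, K = values.shape

    if method == "block_mean":
        ratio = target_pixel_size / src
        r = round(ratio)
        if r < 1 or not math.isclose(ratio, r, rel_tol=1e-9):
            raise ValueError(
                f"block_mean needs an integer target/source ratio, got {ratio}"
            )
        Hc, Wc = (H // r) * r, (W // r) * r
        v = np.where(mask[:, :, None], 0.0, values)[:Hc, :Wc]
        m = (~mask[:Hc, :Wc]).astype(np.float64)
        vsum = v.reshape(Hc // r, r, Wc // r, r, K).sum(axis=(1, 3))
        cnt = m.reshape(Hc // r, r, Wc // r, r).sum(axis=(1, 3))
        out_mask = cnt == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            out = vsum / cnt[:, :, None]
        out[out_mask] = np.nan
        return _rebuild(raster, out, out_mask, target_pixel_size, raster.origin)

    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    order = 0 if method == "nearest" else 1
    Ho = max(1, round(H * src / target_pixel_size))
    Wo = max(1, round(W * src / target_pixel_size))
    t = target_pixel_size / src
    # Pixel-center alignment: output center (i+0.5)*t maps to source index.
    rows = (np.arange(Ho) + 0.5) * t - 0.5
    cols = (np.arange(Wo) + 0.5) * t - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((Ho, Wo, K))
    for k in range(K):
        filled = _fill_nearest(values[:, :, k], mask)
        out[:, :, k] = ndimage.map_coordinates(
            filled, [rr, cc], order=order, mode="nearest")
    out_mask = ndimage.map_coordinates(
        mask.astype(np.uint8), [rr, cc], order=0, mode="nearest").astype(bool)
    out[out_mask] = np.nan
    return _rebuild(raster, out, out_mask, target_pixel_size, raster.origin)


def _extent(raster):
    H, W = (_raster_planes(raster)[0]).shape[:2]
    x0, y0 = raster.origin
    p = raster.pixel_size
    return x0, y0 - H * p, x0 + W * p, y0  # minx, miny, maxx, maxy


def clip_to_wkt(raster, wkt_polygon: str):
    """Clip a raster to a WKT polygon area of interest.

    The output window is the minimal pixel-aligned rectangle containing the
    intersection of the polygon with the raster extent; pixels whose centers
    fall outside the polygon are set to nodata.
    """
    try:
        geom = shapely.from_wkt(wkt_polygon)
    except Exception as exc:  # shapely raises GEOSException
        raise ValueError(f"unparsable WKT polygon: {exc}") from None
    values, mask = _raster_planes(raster)
    H, W, _ = values.shape
    x0, y0 = raster.origin
    p = raster.pixel_size
    minx, miny, maxx, maxy = _extent(raster)
    gx0, gy0, gx1, gy1 = geom.bounds
    ix0 = max(0, math.floor((gx0 - x0) / p))
    ix1 = min(W, math.ceil((gx1 - x0) / p))
    # row 0 is at maxy; rows grow southwards
    ir0 = max(0, math.floor((y0 - gy1) / p))
    ir1 = min(H, math.ceil((y0 - gy0) / p))
    if ix0 >= ix1 or ir0 >= ir1:
        raise ValueError("polygon does not intersect the raster extent")
    win_vals = values[ir0:ir1, ix0:ix1].copy()
    win_mask = mask[ir0:ir1, ix0:ix1].copy()
    cx = x0 + (np.arange(ix0, ix1) + 0.5) * p
    cy = y0 - (np.arange(ir0, ir1) + 0.5) * p
    xx, yy = np.meshgrid(cx, cy)
    inside = shapely.intersects_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not inside.any():
        raise ValueError("polygon does not cover any pixel center")
    win_mask |= ~inside
    win_vals[win_mask] = np.nan
    new_origin = (x0 + ix0 * p, y0 - ir0 * p)
    return _rebuild(raster, win_vals, win_mask, p, new_origin)


def check_aligned(scene: MultispectralScene, agb: AGBRaster) -> None:
    """Verify that a scene and an AGB raster live on the same grid.

    Tolerates origin offsets up to half a pixel; anything larger means the
    products were not co-registered and must be resampled first.
    """
    if scene.shape != agb.shape:
        raise AlignmentError(
            f"grid shapes differ: scene {scene.shape} vs AGB {agb.shape}")
    if not math.isclose(scene.pixel_size, agb.pixel_size, rel_tol=1e-6):
        raise AlignmentError(
            f"pixel sizes differ: {scene.pixel_size} vs {agb.pixel_size}")
    tol = 0.5 * scene.pixel_size
    dx = abs(scene.origin[0] - agb.origin[0])
    dy = abs(scene.origin[1] - agb.origin[1])
    if dx > tol or dy > tol:
        raise AlignmentError(
            f"origins differ by ({dx:.2f}, {dy:.2f}) m > half a pixel")


# ---------------------------------------------------------------------------
# TIFF I/O (JSON georeferencing sidecar in the ImageDescription tag)

def _meta(raster, kind):
    meta = {
        "kind": kind,
        "pixel_size": raster.pixel_size,
        "origin": list(raster.origin),
        "crs_id": raster.crs_id,
        "nodata": "nan",
    }
    if kind == "scene":
        meta["band_labels"] = list(raster.band_labels)
        if raster.acquisition_date is not None:
            meta["acquisition_date"] = raster.acquisition_date.isoformat()
    return meta


def write_raster(path, raster) -> None:
    """Write a scene or AGB raster as a TIFF with JSON georeferencing."""
    if isinstance(raster, MultispectralScene):
        data = np.moveaxis(raster.values, 2, 0).astype(np.float32)
        kind = "scene"
    else:
        data = raster.values.astype(np.float32)
        kind = "agb"
    tifffile.imwrite(str(path), np.ascontiguousarray(data),
                     description=json.dumps(_meta(raster, kind)))


def _read(path):
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        meta = {}
    return data.astype(np.float64), meta


def read_scene(path) -> MultispectralScene:
    data, meta = _read(path)
    if data.ndim == 2:
        data = data[None]
    values = np.moveaxis(data, 0, 2)
    date = meta.get("acquisition_date")
    return MultispectralScene(
        values=values,
        band_labels=meta.get("band_labels",
                             [f"band_{i}" for i in range(values.shape[2])]),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs_id=meta.get("crs_id", "local"),
        acquisition_date=_dt.date.fromisoformat(date) if date else None,
    )


def read_agb(path) -> AGBRaster:
    data, meta = _read(path)
    if data.ndim == 3:
        data = data[0]
    return AGBRaster(
        values=data,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs_id=meta.get("crs_id", "local"),
    )
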