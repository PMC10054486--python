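"""Synthetic co-registered scene/biomass pairs with known structure.

The generator emulates the statistical shape of the real training material:
a spatially autocorrelated landcover field (smoothed Gaussian noise
quantized into classes), class-specific spectral signatures with per-band
noise, and a biomass surface that is a *known, configurable* function of
the realized bands plus noise, with nodata injected at a stated fraction.
Because the biomass-generating function is known, recovery experiments have
an exact reference: with zero noise an ordinary regression on the bands (or
on the index the function uses) attains R² = 1, and any competent learner
must approach it.

One master seed spawns independent substreams for the class field, the band
noise, the biomass noise and the nodata mask, so each component can be
varied without perturbing the others. The same seed and spec always yield
bit-identical rasters.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geodata import AGBRaster, MultispectralScene

__all__ = ["SyntheticSpec", "generate_scene", "DEFAULT_SIGNATURES",
           "BAND_LABELS_10"]

#: The 10 channels retained for the model input.
BAND_LABELS_10 = ("B02", "B03", "B04", "B05", "B06", "B07",
                  "B08", "B8A", "B11", "B12")

#: Mean reflectance per class (water, bare/urban, grassland, forest) for the
#: 10 retained bands — plausible level-2A magnitudes.
DEFAULT_SIGNATURES = np.array([
    [0.06, 0.05, 0.04, 0.03, 0.02, 0.02, 0.01, 0.01, 0.005, 0.005],
    [0.12, 0.14, 0.16, 0.18, 0.20, 0.21, 0.22, 0.23, 0.30, 0.28],
    [0.04, 0.07, 0.06, 0.12, 0.25, 0.30, 0.33, 0.35, 0.20, 0.10],
    [0.03, 0.05, 0.04, 0.08, 0.20, 0.28, 0.32, 0.34, 0.15, 0.07],
])

#: Default biomass model: affine in an NDVI-like ratio with class-specific
#: intercepts (water, bare, grassland, forest), slope in Mg/ha per unit NDVI.
DEFAULT_AGB_MODEL = {
    "kind": "ndvi_affine",
    "intercepts": (0.0, 0.0, 30.0, 120.0),
    "slope": 180.0,
}


@dataclass
class SyntheticSpec:
    """Generator conditions; defaults emulate a 100 m temperate scene."""

    height: int = 256
    width: int = 256
    n_classes: int = 4
    smoothness: float = 8.0          # correlation length of the class field, px
    class_fractions: tuple | None = None
    band_signatures: np.ndarray | None = None   # (n_classes, 10) means
    band_noise_sd: float = 0.01      # reflectance units, per band
    agb_model: dict = field(default_factory=lambda: dict(DEFAULT_AGB_MODEL))
    agb_noise_sd: float = 10.0       # Mg/ha
    nodata_fraction: float = 0.02
    pixel_size: float = 100.0        # m; the training grid of the AGB product
    seed: int = 0

    def __post_init__(self):
        if self.smoothness >= min(self.height, self.width):
            raise ValueError(
                "smoothness must be smaller than the raster: the class "
                "field would be degenerate")
        if self.band_signatures is None:
            reps = -(-self.n_classes // len(DEFAULT_SIGNATURES))
            self.band_signatures = np.tile(
                DEFAULT_SIGNATURES, (reps, 1))[:self.n_classes]
        self.band_signatures = np.asarray(self.band_signatures, float)
        if self.band_signatures.shape != (self.n_classes, 10):
            raise ValueError("band_signatures must be (n_classes, 10)")
        if self.class_fractions is None:
            self.class_fractions = tuple(
                [1.0 / self.n_classes] * self.n_classes)
        if not np.isclose(sum(self.class_fractions), 1.0):
            raise ValueError("class fractions must sum to 1")


def _agb_function(bands: np.ndarray, class_map: np.ndarray,
                  model: dict) -> np.ndarray:
    """Evaluate the configured biomass model g(bands) (no noise)."""
    kind = model.get("kind", "ndvi_affine")
    if kind == "ndvi_affine":
        nir = bands[:, :, BAND_LABELS_10.index("B08")]
        red = bands[:, :, BAND_LABELS_10.index("B04")]
        denom = nir + red
        ndvi = np.where(denom == 0, 0.0,
                        (nir - red) / np.where(denom == 0, 1.0, denom))
        icpt = np.asarray(model["intercepts"], float)[class_map]
        return icpt + model["slope"] * ndvi
    if kind == "affine":
        w = np.asarray(model["weights"], float)
        return model.get("intercept", 0.0) + bands @ w
    raise ValueError(f"unknown agb model kind {kind!r}")


def generate_scene(spec: SyntheticSpec):
    """Draw one (scene, AGB raster, class map) triple from the spec.

    The class field is Gaussian noise smoothed at the spec's correlation
    length and quantized at the class-fraction quantiles, giving contiguous
    regions with the requested areas. Reflectances are clipped to [0, 1.5]
    and biomass to ≥ 0.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_field, rng_band, rng_agb, rng_nodata = (
        np.random.default_rng(s) for s in ss.spawn(4))
    H, W = spec.height, spec.width

    field_raw = ndimage.gaussian_filter(
        rng_field.standard_normal((H, W)), sigma=spec.smoothness,
        mode="reflect")
    cuts = np.quantile(field_raw,
                       np.cumsum(spec.class_fractions)[:-1])
    class_map = np.searchsorted(cuts, field_raw, side="right")

    bands = spec.band_signatures[class_map]          # (H, W, 10)
    bands = bands + rng_band.normal(0.0, spec.band_noise_sd,
                                    size=bands.shape)
    bands = np.clip(bands, 0.0, 1.5)

    agb_true = _agb_function(bands, class_map, spec.agb_model)
    if spec.agb_noise_sd > 0:
        agb_true = agb_true + rng_agb.normal(0.0, spec.agb_noise_sd,
                                             size=agb_true.shape)
    agb_true = np.maximum(agb_true, 0.0)

    scene_mask = np.zeros((H, W), dtype=bool)
    agb_mask = np.zeros((H, W), dtype=bool)
    if spec.nodata_fraction > 0:
        scene_mask = rng_nodata.random((H, W)) < spec.nodata_fraction
        agb_mask = rng_nodata.random((H, W)) < spec.nodata_fraction
    bands = np.where(scene_mask[:, :, None], np.nan, bands)
    agb_vals = np.where(agb_mask, np.nan, agb_true)

    origin = (300000.0, 5600000.0)
    scene = MultispectralScene(
        values=bands, band_labels=BAND_LABELS_10,
        pixel_size=spec.pixel_size, origin=origin, crs_id="EPSG:32632",
        acquisition_date=_dt.date(2018, 7, 27), nodata_mask=scene_mask)
    agb = AGBRaster(values=agb_vals, pixel_size=spec.pixel_size,
                    origin=origin, crs_id="EPSG:32632",
                    nodata_mask=agb_mask)
    return scene, agb, class_map
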