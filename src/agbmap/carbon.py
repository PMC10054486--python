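"""Carbon-stock accounting from predicted biomass rasters.

The procedure aggregates a 10 m AGB prediction into one-hectare cells
(10×10 pixels), takes each cell's mean biomass density in Mg/ha — which
over one hectare is directly a mass in tons — sums over cells, and converts
dry biomass to stored carbon with the standard carbon fraction of 0.5.
Because the biomass product excludes roots, a root-to-shoot correction adds
a configurable fraction (0.3 for temperate oak forest) of the above-ground
carbon:  total = (1 + root_fraction) × above-ground carbon.

Negative predictions (possible from the linear network head) are clamped to
zero here, at reporting, not in the model. Partial hectare cells at the
raster margins contribute their valid-pixel mean scaled by their true area
fraction so margins never inflate totals. All internal values are double
precision; rounding to whole tons happens only in the rendered report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geodata import AGBRaster

__all__ = ["CarbonReport", "CarbonDelta", "carbon_stock", "change_report",
           "CARBON_FRACTION"]

#: Fraction of dry above-ground biomass that is carbon.
CARBON_FRACTION = 0.5

#: Pixels per hectare-cell side at the 10 m inference resolution.
_CELL = 10


@dataclass
class CarbonReport:
    """Per-hectare biomass means and the derived carbon totals (tons)."""

    hectare_means: np.ndarray        # (h, w) mean AGB per cell, Mg/ha
    hectare_area: np.ndarray         # (h, w) cell area in ha (<1 at margins)
    total_agb: float                 # tons of dry above-ground biomass
    aboveground_carbon: float        # tons, = 0.5 × total_agb
    root_fraction: float
    total_carbon_with_roots: float   # tons, = (1 + rf) × AGC
    date: object = None

    def rounded(self) -> dict:
        """Presentation values, rounded to the nearest whole ton."""
        return {
            "total_agb_t": round(self.total_agb),
            "aboveground_carbon_t": round(self.aboveground_carbon),
            "total_carbon_with_roots_t": round(self.total_carbon_with_roots),
        }

    def render(self) -> str:
        r = self.rounded()
        lines = []
        if self.date is not None:
            lines.append(f"date: {self.date}")
        lines += [
            f"total above-ground biomass: {r['total_agb_t']:,} t",
            f"above-ground carbon (x {CARBON_FRACTION}): "
            f"{r['aboveground_carbon_t']:,} t",
            f"root fraction: {self.root_fraction}",
            "total carbon incl. roots "
            f"(x {1 + self.root_fraction:.1f}): "
            f"{r['total_carbon_with_roots_t']:,} t",
        ]
        return "\n".join(lines)


def carbon_stock(agb: AGBRaster, root_fraction: float = 0.3,
                 date=None) -> CarbonReport:
    """Aggregate a 10 m AGB raster into carbon totals.

    Raises unless the raster is on the 10 m grid — coarser predictions must
    be resampled first so a 10×10 block is exactly one hectare.
    """
    if not math.isclose(agb.pixel_size, 10.0, rel_tol=1e-6):
        raise ValueError(
            f"carbon accounting expects a 10 m grid, got "
            f"{agb.pixel_size} m; resample the prediction first")
    if root_fraction < 0:
        raise ValueError("root_fraction must be non-negative")
    H, W = agb.shape
    h, w = H // _CELL, W // _CELL
    if h == 0 or w == 0:
        raise ValueError("raster smaller than one hectare cell")
    vals = np.where(agb.nodata_mask, 0.0, np.maximum(agb.values, 0.0))
    cnt = (~agb.nodata_mask).astype(np.float64)

    def blocks(a):
        return a[:h * _CELL, :w * _CELL].reshape(
            h, _CELL, w, _CELL).sum(axis=(1, 3))

    vsum, vcnt = blocks(vals), blocks(cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(vcnt > 0, vsum / np.where(vcnt > 0, vcnt, 1), np.nan)
    # full cells: valid-pixel mean (Mg/ha) × 1 ha each
    total_agb = float(np.where(vcnt > 0, means, 0.0).sum())
    area = np.where(vcnt > 0, 1.0, 0.0)
    # margin blocks narrower than a cell: mean × geometric area fraction
    margins = []
    if H % _CELL:
        margins += [(slice(h * _CELL, H), slice(j * _CELL,
                     min((j + 1) * _CELL, W)))
                    for j in range(-(-W // _CELL))]
    if W % _CELL:
        margins += [(slice(i * _CELL, (i + 1) * _CELL),
                     slice(w * _CELL, W)) for i in range(h)]
    for rs, cs in margins:
        c = cnt[rs, cs].sum()
        if c == 0:
            continue
        npix = (rs.stop - rs.start) * (cs.stop - cs.start)
        total_agb += float(vals[rs, cs].sum() / c * npix / (_CELL * _CELL))
    agc = CARBON_FRACTION * total_agb
    return CarbonReport(
        hectare_means=means, hectare_area=area, total_agb=total_agb,
        aboveground_carbon=agc, root_fraction=root_fraction,
        total_carbon_with_roots=(1.0 + root_fraction) * agc, date=date)


@dataclass
class CarbonDelta:
    """Before/after change record (after − before), totals in tons."""

    hectare_delta: np.ndarray
    delta_total_agb: float
    delta_aboveground_carbon: float
    delta_total_carbon_with_roots: float
    pct_change_aboveground_carbon: float

    def render(self) -> str:
        return "\n".join([
            f"change in above-ground biomass: "
            f"{round(self.delta_total_agb):,} t",
            f"change in above-ground carbon: "
            f"{round(self.delta_aboveground_carbon):,} t "
            f"({self.pct_change_aboveground_carbon:+.1f}%)",
            f"change in total carbon incl. roots: "
            f"{round(self.delta_total_carbon_with_roots):,} t",
        ])


def change_report(before: CarbonReport, after: CarbonReport) -> CarbonDelta:
    """Difference of two carbon reports on the same hectare grid."""
    if before.hectare_means.shape != after.hectare_means.shape:
        raise ValueError("carbon reports cover different hectare grids")
    if before.root_fraction != after.root_fraction:
        raise ValueError("carbon reports use different root fractions")
    pct = (math.nan if before.aboveground_carbon == 0 else
           100.0 * (after.aboveground_carbon - before.aboveground_carbon)
           / before.aboveground_carbon)
    return CarbonDelta(
        hectare_delta=after.hectare_means - before.hectare_means,
        delta_total_agb=after.total_agb - before.total_agb,
        delta_aboveground_carbon=(after.aboveground_carbon
                                  - before.aboveground_carbon),
        delta_total_carbon_with_roots=(after.total_carbon_with_roots
                                       - before.total_carbon_with_roots),
        pct_change_aboveground_carbon=pct)
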