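"""Random-forest competitor pipelines over engineered per-pixel features.

Both literature baselines regress biomass pixel by pixel from a feature
table; spatial context enters only through the windowed texture features.
Competitor 1 uses the raw bands plus spectral indices plus the 8 GLCM
statistics; competitor 2 uses spectral indices plus the 8 GLCM statistics
plus the 9 wavelet detail planes. All textures are computed on PC1. The
original studies' exact variable inventories (132 variables, 42/11 index
lists) are not fully enumerable; the registry shipped here is a documented
approximation with the same structure.

The forests are maximally grown, consider floor(sqrt(F)) candidate features
per split, and the tree count is selected on the validation fold from
{250, 500} (ties prefer the smaller forest). Pixels inherit the fold of the
patch that contains them, so the evaluation is paired with the network's and
leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import (DEFAULT_INDEX_REGISTRY, FeatureStack,
                       first_principal_component, glcm_features,
                       spectral_indices, wavelet_textures)
from .geodata import AGBRaster, MultispectralScene, check_aligned
from .patching import FoldAssignment, PatchSet
from .training import MetricsReport, compute_metrics

__all__ = ["RFConfig", "build_feature_table", "rf_fit_select",
           "rf_cross_validate", "FEATURE_SETS"]

FEATURE_SETS = ("competitor1", "competitor2")


@dataclass
class RFConfig:
    """Random-forest settings; invariants follow the stated protocol."""

    n_trees: int = 250
    feature_set: str = "competitor1"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees not in (250, 500):
            raise ValueError("n_trees must be 250 or 500")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")

    @staticmethod
    def features_per_split(n_features: int) -> int:
        """floor(sqrt(F)), the split-candidate count used by every tree."""
        if n_features < 1:
            raise ValueError("need at least one feature")
        return max(1, int(np.floor(np.sqrt(n_features))))


def build_feature_table(scene: MultispectralScene, feature_set: str,
                        glcm_window: int = 5):
    """Per-pixel predictor table for one competitor pipeline.

    Returns ``(table, pixel_rc)`` where ``table`` is a DataFrame with one
    row per valid pixel in raster-scan order and ``pixel_rc`` the (row, col)
    coordinates of those pixels.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    valid = ~scene.nodata_mask
    if not valid.any():
        raise ValueError("scene has no valid pixels")
    pc1 = first_principal_component(scene)
    glcm = glcm_features(pc1, window=glcm_window, valid=valid)
    indices = spectral_indices(scene, DEFAULT_INDEX_REGISTRY)
    stacks = []
    if feature_set == "competitor1":
        stacks.append(FeatureStack(planes=scene.values,
                                   names=scene.band_labels))
        stacks.extend([indices, glcm])
    else:
        wav = wavelet_textures(pc1, wavelet="coif1", levels=3)
        stacks.extend([indices, glcm, wav])
    stack = FeatureStack.concatenate(stacks)
    rows = stack.planes[valid]
    rc = np.argwhere(valid)
    table = pd.DataFrame(rows, columns=list(stack.names))
    # windowed textures around a valid center can still touch filled pixels;
    # any residual non-finite cells get the column median
    table = table.fillna(table.median())
    return table, rc


def rf_fit_select(train_table, train_y, val_table, val_y, *,
                  seed: int = 0, tree_grid=(250, 500)):
    """Fit both tree counts, keep the one with lower validation MAE.

    Ties choose the smaller forest. Trees are maximally grown
    (``max_depth=None``) with floor(sqrt(F)) features per split.
    """
    train_y = np.asarray(train_y, dtype=np.float64)
    if np.unique(train_y).size < 2:
        raise ValueError("degenerate single-valued training target")
    best = None
    for n_trees in sorted(tree_grid):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_depth=None, max_features="sqrt",
            random_state=seed, n_jobs=1)
        rf.fit(train_table, train_y)
        val_mae = float(np.abs(rf.predict(val_table) - val_y).mean())
        if best is None or val_mae < best[0]:
            best = (val_mae, n_trees, rf)
    return {"model": best[2], "n_trees": best[1], "val_mae": best[0]}


def _pixel_folds(rc: np.ndarray, patchset: PatchSet,
                 folds: FoldAssignment) -> np.ndarray:
    """Fold of each pixel = fold of the patch containing it (-1 if none)."""
    lookup = {}
    for anchor, f in zip(map(tuple, patchset.anchors), folds.fold_of):
        lookup[anchor] = f
    P = patchset.patch_size
    out = np.full(len(rc), -1, dtype=int)
    for i, (r, c) in enumerate(rc):
        out[i] = lookup.get((r // P * P, c // P * P), -1)
    return out


def rf_cross_validate(scene: MultispectralScene, agb: AGBRaster,
                      patchset: PatchSet, folds: FoldAssignment,
                      feature_set: str, seed: int = 0,
                      max_train_pixels: int | None = None,
                      test_folds=None) -> MetricsReport:
    """Evaluate a competitor on the identical spatial folds as the network."""
    check_aligned(scene, agb)
    table, rc = build_feature_table(scene, feature_set)
    y = agb.values[tuple(rc.T)]
    target_ok = ~agb.nodata_mask[tuple(rc.T)]
    pix_fold = _pixel_folds(rc, patchset, folds)
    usable = (pix_fold >= 0) & target_ok
    rng = np.random.default_rng(seed)
    rows = []
    n_folds = folds.n_folds
    iterations = range(n_folds) if test_folds is None else test_folds
    for k in iterations:
        val_f = (k + 1) % n_folds
        tr = usable & (pix_fold != k) & (pix_fold != val_f)
        va = usable & (pix_fold == val_f)
        te = usable & (pix_fold == k)
        if not (tr.any() and va.any() and te.any()):
            raise ValueError(f"fold {k}: empty train/val/test pixel set")
        tr_idx = np.flatnonzero(tr)
        if max_train_pixels is not None and len(tr_idx) > max_train_pixels:
            tr_idx = rng.choice(tr_idx, size=max_train_pixels, replace=False)
        fit = rf_fit_select(table.iloc[tr_idx], y[tr_idx],
                            table.iloc[np.flatnonzero(va)], y[va],
                            seed=seed * 613 + k)
        pred = fit["model"].predict(table.iloc[np.flatnonzero(te)])
        mae, rmse, r2 = compute_metrics(pred, y[te])
        rows.append({"fold": k, "mae": mae, "rmse": rmse, "r2": r2,
                     "n_trees": fit["n_trees"]})
    return MetricsReport(model_name=feature_set,
                         per_fold=pd.DataFrame(rows))
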