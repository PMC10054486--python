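"""Patch extraction, spatially blocked fold assignment, and reassembly.

The network is trained patch-wise: co-registered scene/AGB rasters are cut
into non-overlapping 16×16 tiles, each tile carrying its input block, its
target block and a per-pixel validity mask. Folds for cross-validation are
*spatial blocks*: the patch grid is split into contiguous rectangular zones,
one zone per fold, so that training, validation and test data come from
disjoint portions of the map and spatial autocorrelation cannot leak across
the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata import AGBRaster, MultispectralScene, check_aligned

__all__ = ["PatchSet", "FoldAssignment", "extract_patches", "reassemble",
           "assign_folds", "save_patchset", "load_patchset"]

log = logging.getLogger(__name__)


@dataclass
class PatchSet:
    """Aligned input/target patch pairs cut from one scene.

    anchors are (row, col) offsets of each patch's top-left pixel in the
    source grid; all are multiples of ``patch_size`` so patches never
    overlap. ``valid_mask`` is True where both the scene and the target are
    valid.
    """

    patch_size: int
    anchors: np.ndarray          # (N, 2) int
    X: np.ndarray                # (N, P, P, C)
    Y: np.ndarray                # (N, P, P)
    valid_mask: np.ndarray       # (N, P, P) bool
    source_shape: tuple          # (H, W) of the source grid
    pixel_size: float = 1.0
    origin: tuple = (0.0, 0.0)
    crs_id: str = "local"

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=int)
        n = len(self.anchors)
        if not (len(self.X) == len(self.Y) == len(self.valid_mask) == n):
            raise ValueError("patch arrays must have equal length")
        if n and (self.anchors % self.patch_size).any():
            raise ValueError("anchors must be multiples of the patch size")

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def n_channels(self) -> int:
        return self.X.shape[3]

    def grid_coords(self) -> np.ndarray:
        """Patch coordinates on the patch grid (anchor // patch size)."""
        return self.anchors // self.patch_size


@dataclass
class FoldAssignment:
    """Zone-respecting fold labels for a :class:`PatchSet`."""

    n_folds: int
    fold_of: np.ndarray     # (N,) int in [0, n_folds)
    zone_of: np.ndarray     # (N,) int; every zone maps to exactly one fold

    def __post_init__(self):
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        self.zone_of = np.asarray(self.zone_of, dtype=int)
        if self.fold_of.shape != self.zone_of.shape:
            raise ValueError("fold_of / zone_of length mismatch")
        for f in range(self.n_folds):
            if not (self.fold_of == f).any():
                raise ValueError(f"fold {f} is empty")
        # a zone must not straddle folds
        for z in np.unique(self.zone_of):
            if len(np.unique(self.fold_of[self.zone_of == z])) != 1:
                raise ValueError(f"zone {z} is split across folds")

    def members(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def extract_patches(scene: MultispectralScene, agb: AGBRaster,
                    patch_size: int = 16) -> PatchSet:
    """Cut a co-registered scene/AGB pair into non-overlapping patches.

    Right/bottom margins narrower than the patch size are discarded (their
    extent is logged); patches whose target block is entirely nodata are
    dropped. Partially valid patches are kept with their mask.
    """
    check_aligned(scene, agb)
    P = int(patch_size)
    H, W = scene.shape
    if H < P or W < P:
        raise ValueError(f"raster {H}×{W} smaller than patch size {P}")
    nr, nc = H // P, W // P
    if H % P or W % P:
        log.info("dropping margins: %d rows, %d cols (not divisible by %d)",
                 H % P, W % P, P)
    anchors, xs, ys, ms = [], [], [], []
    valid = ~(scene.nodata_mask | agb.nodata_mask)
    for i in range(nr):
        for j in range(nc):
            r0, c0 = i * P, j * P
            m = valid[r0:r0 + P, c0:c0 + P]
            if not m.any():
                continue
            anchors.append((r0, c0))
            xs.append(scene.values[r0:r0 + P, c0:c0 + P])
            ys.append(agb.values[r0:r0 + P, c0:c0 + P])
            ms.append(m)
    if not anchors:
        raise ValueError("no patch contains a valid target pixel")
    X = np.stack(xs)
    Y = np.stack(ys)
    M = np.stack(ms)
    X = np.where(M[:, :, :, None], X, 0.0)
    Y = np.where(M, Y, 0.0)
    return PatchSet(patch_size=P, anchors=np.array(anchors), X=X, Y=Y,
                    valid_mask=M, source_shape=(H, W),
                    pixel_size=scene.pixel_size, origin=scene.origin,
                    crs_id=scene.crs_id)


def reassemble(predictions: np.ndarray, anchors, out_shape,
               patch_size: int | None = None, *, pixel_size: float = 1.0,
               origin=(0.0, 0.0), crs_id: str = "local",
               valid_mask: np.ndarray | None = None) -> AGBRaster:
    """Stitch per-patch predictions back into a full raster.

    Every pixel covered by a patch receives exactly one value; margins not
    covered by any patch (and pixels invalid in ``valid_mask``, if given)
    are nodata.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.ndim == 4 and predictions.shape[3] == 1:
        predictions = predictions[:, :, :, 0]
    anchors = np.asarray(anchors, dtype=int)
    if len(anchors) != len(predictions):
        raise ValueError("one anchor per patch required")
    if len(np.unique(anchors, axis=0)) != len(anchors):
        raise ValueError("duplicate patch anchors")
    P = patch_size or predictions.shape[1]
    H, W = out_shape
    values = np.full((H, W), np.nan)
    mask = np.ones((H, W), dtype=bool)
    for k, (r0, c0) in enumerate(anchors):
        if r0 < 0 or c0 < 0 or r0 + P > H or c0 + P > W:
            raise ValueError(f"anchor {(r0, c0)} outside output shape")
        block_valid = np.ones((P, P), bool) if valid_mask is None \
            else valid_mask[k]
        v = np.where(block_valid, predictions[k], np.nan)
        values[r0:r0 + P, c0:c0 + P] = v
        mask[r0:r0 + P, c0:c0 + P] = ~block_valid
    return AGBRaster(values=values, pixel_size=pixel_size, origin=origin,
                     crs_id=crs_id, nodata_mask=mask, kind="prediction")


def _block_grid(n_folds: int, grid_h: int, grid_w: int) -> tuple:
    """Pick the r×c arrangement of zones best matching the grid aspect."""
    best = None
    for r in range(1, n_folds + 1):
        if n_folds % r:
            continue
        c = n_folds // r
        if r > grid_h or c > grid_w:
            continue
        # compare zone aspect to patch-grid aspect in log space
        score = abs(np.log((grid_h / r) / (grid_w / c)))
        if best is None or score < best[0]:
            best = (score, r, c)
    if best is None:
        raise ValueError(
            f"cannot tile a {grid_h}×{grid_w} patch grid into {n_folds} zones")
    return best[1], best[2]


def assign_folds(patchset: PatchSet, n_folds: int = 8,
                 scheme: str = "contiguous_blocks") -> FoldAssignment:
    """Partition patches into spatially contiguous zones, one per fold.

    The patch grid is tiled by an r×c arrangement of contiguous rectangles
    with r·c = n_folds (aspect chosen to match the grid); every patch of a
    zone shares that zone's fold, so each fold is a distinct portion of the
    map.
    """
    if scheme != "contiguous_blocks":
        raise ValueError(f"unknown fold scheme {scheme!r}")
    if len(patchset) < n_folds:
        raise ValueError(
            f"{len(patchset)} patches cannot fill {n_folds} folds")
    coords = patchset.grid_coords()
    grid_h = patchset.source_shape[0] // patchset.patch_size
    grid_w = patchset.source_shape[1] // patchset.patch_size
    r, c = _block_grid(n_folds, grid_h, grid_w)
    row_edges = np.linspace(0, grid_h, r + 1).round().astype(int)
    col_edges = np.linspace(0, grid_w, c + 1).round().astype(int)
    zi = np.searchsorted(row_edges, coords[:, 0], side="right") - 1
    zj = np.searchsorted(col_edges, coords[:, 1], side="right") - 1
    zone = zi * c + zj
    return FoldAssignment(n_folds=n_folds, fold_of=zone, zone_of=zone)


def save_patchset(directory, patchset: PatchSet,
                  folds: FoldAssignment | None = None) -> None:
    """Write a patch set as blocks (npz) plus a plain-text index.

    The index has one line per patch: anchor row, anchor col, zone, fold
    (-1 when no fold assignment is given).
    """
    import json
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "blocks.npz", X=patchset.X, Y=patchset.Y,
             valid_mask=patchset.valid_mask, anchors=patchset.anchors)
    meta = {"patch_size": patchset.patch_size,
            "source_shape": list(patchset.source_shape),
            "pixel_size": patchset.pixel_size,
            "origin": list(patchset.origin), "crs_id": patchset.crs_id}
    if folds is not None:
        meta["n_folds"] = folds.n_folds
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    with open(directory / "index.txt", "w") as fh:
        fh.write("# anchor_row anchor_col zone fold\n")
        for i, (r, c) in enumerate(patchset.anchors):
            z = folds.zone_of[i] if folds is not None else -1
            f = folds.fold_of[i] if folds is not None else -1
            fh.write(f"{r} {c} {z} {f}\n")


def load_patchset(directory):
    """Read back what :func:`save_patchset` wrote -> (PatchSet, folds|None)."""
    import json
    import pathlib

    directory = pathlib.Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    with np.load(directory / "blocks.npz") as data:
        ps = PatchSet(patch_size=meta["patch_size"], anchors=data["anchors"],
                      X=data["X"], Y=data["Y"],
                      valid_mask=data["valid_mask"],
                      source_shape=tuple(meta["source_shape"]),
                      pixel_size=meta["pixel_size"],
                      origin=tuple(meta["origin"]), crs_id=meta["crs_id"])
    folds = None
    if "n_folds" in meta:
        rows = np.loadtxt(directory / "index.txt", dtype=int, ndmin=2)
        folds = FoldAssignment(n_folds=meta["n_folds"],
                               fold_of=rows[:, 3], zone_of=rows[:, 2])
    return ps, folds
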