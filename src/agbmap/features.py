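"""Engineered per-pixel predictors: PC1, GLCM textures, wavelet details, indices.

These are the variables the feature-based pipelines consume. Texture is
computed on the first principal component of the band stack; the gray-level
co-occurrence matrix (GLCM) statistics use a sliding window — at the 100 m
training resolution the default 5×5 window spans 500 m × 500 m of ground —
and the multi-resolution texture comes from a three-level discrete wavelet
decomposition whose horizontal/vertical/diagonal detail images are upsampled
back to the pixel grid.

GLCM conventions (the window size is the only externally fixed choice; the
rest are the standard Haralick defaults): gray levels quantized to 32 bins
by global min–max, symmetric co-occurrence counts, 4 offsets at distance 1
(0°, 45°, 90°, 135°), statistics computed per offset and then averaged,
reflect padding at borders. For a window whose gray-level distribution is
degenerate the correlation is defined as 0.
"""

from __future__ import annotations

import ast
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

from .geodata import MultispectralScene

__all__ = [
    "FeatureStack", "first_principal_component", "glcm_features",
    "wavelet_textures", "spectral_indices", "feature_augmented_scene",
    "DEFAULT_INDEX_REGISTRY", "GLCM_FEATURE_NAMES",
]

GLCM_FEATURE_NAMES = (
    "glcm_mean", "glcm_variance", "glcm_homogeneity", "glcm_contrast",
    "glcm_dissimilarity", "glcm_entropy", "glcm_second_moment",
    "glcm_correlation",
)

#: Offsets at distance 1: 0°, 45°, 90°, 135° (row, col).
_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class FeatureStack:
    """Named per-pixel feature planes aligned with their source raster."""

    planes: np.ndarray          # (H, W, F)
    names: tuple
    provenance: tuple = ()

    def __post_init__(self):
        self.names = tuple(self.names)
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if self.planes.shape[2] != len(self.names):
            raise ValueError("one name per plane required")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def plane(self, name: str) -> np.ndarray:
        return self.planes[:, :, self.names.index(name)]

    @staticmethod
    def concatenate(stacks) -> "FeatureStack":
        return FeatureStack(
            planes=np.concatenate([s.planes for s in stacks], axis=2),
            names=sum((s.names for s in stacks), ()),
            provenance=sum((tuple(s.provenance) for s in stacks), ()),
        )


# ---------------------------------------------------------------------------
# PC1

def first_principal_component(scene: MultispectralScene) -> np.ndarray:
    """Project each pixel's band vector onto the leading covariance eigenvector.

    The covariance is estimated over valid pixels only; the sign of the
    component is fixed so the loading of the first band is non-negative.
    Invalid pixels are NaN in the returned plane.
    """
    valid = ~scene.nodata_mask
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid pixels for PCA")
    V = scene.values[valid]                      # (n, B)
    mu = V.mean(axis=0)
    Vc = V - mu
    cov = Vc.T @ Vc / (len(Vc) - 1)
    if not (np.diag(cov) > 0).any():
        raise ValueError("all bands constant: principal direction undefined")
    w, U = np.linalg.eigh(cov)
    vec = U[:, -1]
    if vec[0] < 0 or (vec[0] == 0 and vec.sum() < 0):
        vec = -vec
    plane = np.full(scene.shape, np.nan)
    plane[valid] = Vc @ vec
    return plane


# ---------------------------------------------------------------------------
# GLCM

def _quantize(plane: np.ndarray, valid: np.ndarray, levels: int) -> np.ndarray:
    vals = plane[valid]
    lo, hi = vals.min(), vals.max()
    filled = np.where(valid, plane, vals.mean())
    if hi == lo:
        return np.zeros(plane.shape, dtype=np.int64)
    q = np.floor((filled - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _offset_pairs(win: np.ndarray, dr: int, dc: int):
    """All directed co-occurring pairs at (dr, dc) inside each window."""
    h = slice(None, -dr) if dr else slice(None)
    h2 = slice(dr, None) if dr else slice(None)
    if dc > 0:
        v, v2 = slice(None, -dc), slice(dc, None)
    elif dc < 0:
        v, v2 = slice(-dc, None), slice(None, dc)
    else:
        v = v2 = slice(None)
    a = win[:, :, h, v]
    b = win[:, :, h2, v2]
    n = a.shape[2] * a.shape[3]
    return a.reshape(a.shape[0], a.shape[1], n), \
        b.reshape(b.shape[0], b.shape[1], n)


def _entropy_asm(a: np.ndarray, b: np.ndarray, levels: int,
                 chunk: int = 65536):
    """Entropy and angular second moment of the symmetric pair multiset.

    Works from per-entry multiplicities instead of materializing the full
    levels×levels matrix per window: for a matrix built from M entries,
    ASM = Σ m_e / M² over entries and entropy = −Σ (1/M)·log(m_e/M).
    """
    H, W, K = a.shape
    codes = np.concatenate([a * levels + b, b * levels + a], axis=2)
    codes = codes.reshape(H * W, 2 * K)
    M = 2 * K
    ent = np.empty(H * W)
    asm = np.empty(H * W)
    for s in range(0, H * W, max(1, chunk // M)):
        e = codes[s:s + max(1, chunk // M)]
        m = (e[:, :, None] == e[:, None, :]).sum(axis=2)
        asm[s:s + len(e)] = m.sum(axis=1) / (M * M)
        ent[s:s + len(e)] = -np.log(m / M).sum(axis=1) / M
    return ent.reshape(H, W), asm.reshape(H, W)


def glcm_features(plane: np.ndarray, window: int = 5, levels: int = 32,
                  valid: np.ndarray | None = None) -> FeatureStack:
    """Sliding-window Haralick statistics of the gray-level co-occurrence matrix.

    Returns 8 planes (mean, variance, homogeneity, contrast, dissimilarity,
    entropy, second moment, correlation), each the average of the per-offset
    statistic over the 4 distance-1 offsets. Border windows use reflect
    padding. Invalid input pixels are filled with the valid mean before
    quantization and masked with NaN in the output.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    plane = np.asarray(plane, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(plane)
    if not valid.any():
        raise ValueError("no valid pixels")
    q = _quantize(plane, valid, levels)
    pad = window // 2
    qp = np.pad(q, pad, mode="reflect")
    win = sliding_window_view(qp, (window, window))
    acc = np.zeros(plane.shape + (8,))
    for dr, dc in _OFFSETS:
        a, b = _offset_pairs(win, dr, dc)
        a = a.astype(np.float64)
        bf = b.astype(np.float64)
        mu = (a.mean(axis=2) + bf.mean(axis=2)) / 2.0
        d = a - bf
        var = (((a - mu[:, :, None]) ** 2).mean(axis=2)
               + ((bf - mu[:, :, None]) ** 2).mean(axis=2)) / 2.0
        contrast = (d ** 2).mean(axis=2)
        dissim = np.abs(d).mean(axis=2)
        homog = (1.0 / (1.0 + d ** 2)).mean(axis=2)
        cov = (a * bf).mean(axis=2) - mu ** 2
        corr = np.where(var > 1e-12, cov / np.where(var > 1e-12, var, 1.0), 0.0)
        ent, asm = _entropy_asm(
            np.ascontiguousarray(a, dtype=np.int64),
            np.ascontiguousarray(b.astype(np.int64)), levels)
        acc[:, :, 0] += mu
        acc[:, :, 1] += var
        acc[:, :, 2] += homog
        acc[:, :, 3] += contrast
        acc[:, :, 4] += dissim
        acc[:, :, 5] += ent
        acc[:, :, 6] += asm
        acc[:, :, 7] += corr
    acc /= len(_OFFSETS)
    acc[~valid] = np.nan
    prov = tuple({"feature": n, "window": window, "levels": levels,
                  "offsets": _OFFSETS} for n in GLCM_FEATURE_NAMES)
    return FeatureStack(planes=acc, names=GLCM_FEATURE_NAMES, provenance=prov)


# ---------------------------------------------------------------------------
# Wavelet textures

def wavelet_textures(plane: np.ndarray, wavelet: str = "coif1",
                     levels: int = 3) -> FeatureStack:
    """Multi-level wavelet detail images as per-pixel texture predictors.

    A ``levels``-level 2-D discrete wavelet decomposition (Coiflet-1 by
    default, symmetric signal extension) yields horizontal, vertical and
    diagonal detail sub-images per level — 9 planes for the default 3
    levels — each replicated back to the source grid by nearest-neighbour
    upsampling (pixel r maps to detail coefficient r // 2**level).
    """
    plane = np.asarray(plane, dtype=np.float64)
    H, W = plane.shape
    if min(H, W) < 2 ** levels:
        raise ValueError(
            f"plane {H}×{W} too small for a {levels}-level decomposition")
    filled = plane
    if not np.isfinite(plane).all():
        m = np.isfinite(plane)
        filled = np.where(m, plane, plane[m].mean() if m.any() else 0.0)
    coeffs = pywt.wavedec2(filled, wavelet, mode="symmetric", level=levels)
    # coeffs = [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]
    planes, names, prov = [], [], []
    for pos, detail in enumerate(coeffs[1:]):
        lev = levels - pos
        ri = np.minimum(np.arange(H) // 2 ** lev, detail[0].shape[0] - 1)
        ci = np.minimum(np.arange(W) // 2 ** lev, detail[0].shape[1] - 1)
        for orient, d in zip(("horizontal", "vertical", "diagonal"), detail):
            planes.append(d[np.ix_(ri, ci)])
            names.append(f"wav_L{lev}_{orient}")
            prov.append({"feature": names[-1], "wavelet": wavelet,
                         "level": lev, "orientation": orient,
                         "mode": "symmetric"})
    order = np.argsort([n.split("_")[1] for n in names], kind="stable")
    stack = np.stack([planes[i] for i in order], axis=2)
    return FeatureStack(planes=stack,
                        names=tuple(names[i] for i in order),
                        provenance=tuple(prov[i] for i in order))


# ---------------------------------------------------------------------------
# Spectral indices

#: Standard vegetation/water indices computable from the 10 retained bands.
DEFAULT_INDEX_REGISTRY = OrderedDict([
    ("ndvi", "(B08 - B04) / (B08 + B04)"),
    ("gndvi", "(B08 - B03) / (B08 + B03)"),
    ("ndwi", "(B03 - B08) / (B03 + B08)"),
    ("ndmi", "(B08 - B11) / (B08 + B11)"),
    ("evi", "2.5 * (B08 - B04) / (B08 + 6 * B04 - 7.5 * B02 + 1)"),
    ("savi", "1.5 * (B08 - B04) / (B08 + B04 + 0.5)"),
    ("ndre1", "(B08 - B05) / (B08 + B05)"),
    ("ndre2", "(B08 - B06) / (B08 + B06)"),
    ("ndre3", "(B08 - B07) / (B08 + B07)"),
    ("cire", "B08 / B05 - 1"),
    ("msi", "B11 / B08"),
])

_ALLOWED_AST = (ast.Expression, ast.BinOp, ast.UnaryOp, ast.Name, ast.Load,
                ast.Constant, ast.Add, ast.Sub, ast.Mult, ast.Div,
                ast.Pow, ast.USub, ast.UAdd)


def _eval_formula(formula: str, bands: dict, index_name: str) -> np.ndarray:
    """Evaluate a rational band expression with divide-by-zero -> 0."""
    tree = ast.parse(formula, mode="eval")
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_AST):
            raise ValueError(
                f"index {index_name!r}: unsupported syntax "
                f"{type(node).__name__} in formula")
        if isinstance(node, ast.Name) and node.id not in bands:
            raise KeyError(
                f"index {index_name!r} references missing band {node.id!r}")

    def ev(node):
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.Name):
            return bands[node.id]
        if isinstance(node, ast.UnaryOp):
            v = ev(node.operand)
            return -v if isinstance(node.op, ast.USub) else +v
        left, right = ev(node.left), ev(node.right)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Pow):
            return left ** right
        # division: 0 where the denominator vanishes, flagged by caller
        denom = np.asarray(right, dtype=np.float64)
        zero = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(zero, 0.0, left / np.where(zero, 1.0, denom))
        ev.divzero = ev.divzero | zero if np.ndim(zero) else ev.divzero
        return out

    ev.divzero = np.zeros(next(iter(bands.values())).shape, dtype=bool)
    return ev(tree), ev.divzero


def feature_augmented_scene(scene: MultispectralScene,
                            glcm_window: int = 5) -> MultispectralScene:
    """Stack engineered features as extra channels onto the raw bands.

    Adds the spectral indices, the 8 GLCM statistics and the 9 wavelet
    detail planes (textures on PC1) — the input of the with-features
    network variant.
    """
    from dataclasses import replace

    pc1 = first_principal_component(scene)
    stacks = [
        spectral_indices(scene),
        glcm_features(pc1, window=glcm_window, valid=~scene.nodata_mask),
        wavelet_textures(pc1),
    ]
    extra = FeatureStack.concatenate(stacks)
    planes = extra.planes.copy()
    # wavelet planes are finite everywhere; index/GLCM planes are NaN only
    # at nodata — normalize that to NaN across all extra channels
    planes[scene.nodata_mask] = np.nan
    return replace(
        scene,
        values=np.concatenate([scene.values, planes], axis=2),
        band_labels=scene.band_labels + extra.names,
        nodata_mask=scene.nodata_mask.copy(),
    )


def spectral_indices(scene: MultispectralScene,
                     registry: "OrderedDict[str, str]" = None) -> FeatureStack:
    """Evaluate a registry of named band-ratio indices per pixel.

    Division-by-zero pixels are set to 0 and recorded in the per-plane
    provenance under ``divzero_count``.
    """
    registry = DEFAULT_INDEX_REGISTRY if registry is None else registry
    bands = {lbl: scene.values[:, :, i]
             for i, lbl in enumerate(scene.band_labels)}
    planes, names, prov = [], [], []
    for name, formula in registry.items():
        vals, divzero = _eval_formula(formula, bands, name)
        vals = np.where(scene.nodata_mask, np.nan, vals)
        planes.append(vals)
        names.append(name)
        prov.append({"feature": name, "formula": formula,
                     "divzero_count": int(divzero[~scene.nodata_mask].sum())})
    return FeatureStack(planes=np.stack(planes, axis=2), names=tuple(names),
                        provenance=tuple(prov))
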