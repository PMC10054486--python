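"""Brute-force GLCM reference, independent of the package implementation.

Builds the symmetric normalized co-occurrence matrix of a quantized window
by explicit dictionary counting, computes the eight Haralick statistics by
direct summation over matrix cells, and averages the statistics over the
four distance-1 offsets — the same convention the package documents, derived
here from first principles.
"""

import math

import numpy as np

OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def quantize(plane, levels):
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane, dtype=int)
    q = np.floor((plane - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def window_stats(window_q):
    """8 statistics for one quantized window (any shape), offset-averaged."""
    h, w = window_q.shape
    per_offset = []
    for dr, dc in OFFSETS:
        counts = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    i, j = int(window_q[r, c]), int(window_q[r2, c2])
                    counts[(i, j)] = counts.get((i, j), 0) + 1
                    counts[(j, i)] = counts.get((j, i), 0) + 1
        total = sum(counts.values())
        p = {k: v / total for k, v in counts.items()}
        mean = sum(i * v for (i, _), v in p.items())
        var = sum((i - mean) ** 2 * v for (i, _), v in p.items())
        contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
        dissim = sum(abs(i - j) * v for (i, j), v in p.items())
        homog = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
        entropy = -sum(v * math.log(v) for v in p.values())
        asm = sum(v ** 2 for v in p.values())
        if var > 1e-12:
            corr = sum((i - mean) * (j - mean) * v
                       for (i, j), v in p.items()) / var
        else:
            corr = 0.0
        per_offset.append((mean, var, homog, contrast, dissim,
                           entropy, asm, corr))
    return np.mean(per_offset, axis=0)


def full_plane_stats(plane, window, levels):
    """Per-pixel statistics with reflect padding, fully brute force."""
    q = quantize(plane, levels)
    pad = window // 2
    qp = np.pad(q, pad, mode="reflect")
    h, w = plane.shape
    out = np.empty((h, w, 8))
    for r in range(h):
        for c in range(w):
            out[r, c] = window_stats(qp[r:r + window, c:c + window])
    return out
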