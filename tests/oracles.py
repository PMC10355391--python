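"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the mathematical definition with plain loops
and numpy primitives, deliberately avoiding the code paths (scipy.ndimage
morphology, uniform filters, skimage labeling) used by the package.
"""
from __future__ import annotations

import numpy as np


def _pad_symmetric(f: np.ndarray, r: int) -> np.ndarray:
    return np.pad(f, r, mode="symmetric")  # matches scipy's "reflect"


def brute_dilation(f: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    r = footprint.shape[0] // 2
    padded = _pad_symmetric(f, r)
    out = np.empty_like(f, dtype=float)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            window = padded[i:i + footprint.shape[0], j:j + footprint.shape[1]]
            out[i, j] = window[footprint].max()
    return out


def brute_erosion(f: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    r = footprint.shape[0] // 2
    padded = _pad_symmetric(f, r)
    out = np.empty_like(f, dtype=float)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            window = padded[i:i + footprint.shape[0], j:j + footprint.shape[1]]
            out[i, j] = window[footprint].min()
    return out


def brute_closing(f, footprint):
    return brute_erosion(brute_dilation(f, footprint), footprint)


def brute_opening(f, footprint):
    return brute_dilation(brute_erosion(f, footprint), footprint)


def brute_wiener(f: np.ndarray, n: int, m: int, v: float) -> np.ndarray:
    """Direct per-pixel evaluation of the local mean/variance Wiener filter."""
    rr, rc = n // 2, m // 2
    padded = np.pad(f, ((rr, rr), (rc, rc)), mode="symmetric")
    out = np.empty_like(f, dtype=float)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            window = padded[i:i + n, j:j + m]
            mu = window.mean()
            var = (window ** 2).mean() - mu ** 2
            var = max(var, 0.0)
            gain = 0.0 if var <= 0 else min(max((var - v) / var, 0.0), 1.0)
            out[i, j] = mu + gain * (f[i, j] - mu)
    return out


_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_binary_dilate8(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for di, dj in _N8:
        shifted = np.zeros_like(mask)
        src = shifted[max(di, 0):mask.shape[0] + min(di, 0),
                      max(dj, 0):mask.shape[1] + min(dj, 0)]
        src |= mask[max(-di, 0):mask.shape[0] + min(-di, 0),
                    max(-dj, 0):mask.shape[1] + min(-dj, 0)]
        out |= shifted
    return out


def brute_reconstruction(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Geodesic dilation (8-connectivity) iterated to the fixpoint."""
    current = marker & mask
    while True:
        grown = brute_binary_dilate8(current) & mask
        if np.array_equal(grown, current):
            return current
        current = grown


def brute_components8(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components by flood fill; returns a list of boolean maps."""
    remaining = mask.copy()
    comps = []
    while remaining.any():
        seed = np.zeros_like(mask)
        i, j = np.argwhere(remaining)[0]
        seed[i, j] = True
        comp = brute_reconstruction(seed, remaining)
        comps.append(comp)
        remaining &= ~comp
    return comps


def brute_area_filter(mask: np.ndarray, min_area: int) -> np.ndarray:
    out = np.zeros_like(mask)
    for comp in brute_components8(mask):
        if comp.sum() >= min_area:
            out |= comp
    return out
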