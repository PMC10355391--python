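"""Shared numeric helpers."""
from __future__ import annotations

import numpy as np


def as_float_image(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return a


def rescale_unit(img: np.ndarray, fov: np.ndarray | None = None,
                 degenerate: str = "half") -> np.ndarray:
    """Min-max rescale to [0,1] using FOV pixels for the range.

    ``degenerate`` controls the constant-image guard: "half" maps a constant
    image to 0.5 everywhere, "keep" returns the input clipped to [0,1].
    """
    img = np.asarray(img, dtype=np.float64)
    sel = img if fov is None else img[np.asarray(fov, bool)]
    lo = float(sel.min())
    hi = float(sel.max())
    if hi - lo < 1e-12:
        if degenerate == "keep":
            return np.clip(img, 0.0, 1.0)
        return np.full_like(img, 0.5)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def check_binary(a: np.ndarray, name: str = "mask") -> np.ndarray:
    a = np.asarray(a)
    if a.dtype != bool:
        u = np.unique(a)
        if not np.all(np.isin(u, (0, 1))):
            raise ValueError(f"{name} must be binary, found values {u[:5]}")
        a = a.astype(bool)
    return a
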