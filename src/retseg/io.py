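"""Raster I/O and image-domain preparation for fundus photographs.

Reads color fundus images (TIFF/PPM/PNG/GIF), binary field-of-view (FOV)
masks and ground-truth vessel maps; writes segmentations as PNG.  Also
prepares the image domain for frequency-domain filtering by continuing the
retinal signal smoothly outside the circular camera aperture, so that the
Fourier stages do not ring against the hard black border.

Coordinates are (row, col), 0-based, origin at the top-left corner.
Intensities are unitless floats in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from ._util import as_float_image, check_binary
from .exceptions import DegenerateMaskError, FormatError

__all__ = [
    "ColorFundusImage",
    "read_fundus_image",
    "read_binary_mask",
    "write_segmentation",
    "extend_border_outside_fov",
    "estimate_fov_mask",
]

_READABLE = {".tif", ".tiff", ".ppm", ".png", ".gif"}


@dataclass(frozen=True)
class ColorFundusImage:
    """An RGB fundus photograph as three [0,1] intensity channels."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self):
        for name in ("red", "green", "blue"):
            ch = as_float_image(getattr(self, name))
            if ch.shape != self.red.shape:
                raise ValueError("channel dimensions differ")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"{name} channel contains non-finite values")
            if ch.min() < 0 or ch.max() > 1:
                raise ValueError(f"{name} channel outside [0,1]")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    def channels(self) -> dict[str, np.ndarray]:
        return {"red": self.red, "green": self.green, "blue": self.blue}


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Scale integer rasters by the dtype's max representable value."""
    if np.issubdtype(arr.dtype, np.integer):
        maxval = np.iinfo(arr.dtype).max
        return arr.astype(np.float64) / maxval
    # float input assumed already in [0,1]
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_fundus_image(path: str | Path) -> ColorFundusImage:
    """Read a fundus photograph into three [0,1] channels.

    Single-channel rasters are replicated into all three channels; an
    alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise FormatError(f"{path}: cannot interpret array of shape {arr.shape}")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise FormatError(f"{path}: unsupported channel count {arr.shape[-1]}")
    scaled = _scale_to_unit(arr)
    return ColorFundusImage(red=scaled[..., 0], green=scaled[..., 1],
                            blue=scaled[..., 2])


def read_binary_mask(path: str | Path, threshold: float = 0.5) -> np.ndarray:
    """Read a single-channel raster as a boolean mask.

    A pixel is true iff its [0,1]-scaled intensity exceeds ``threshold``.
    Raises :class:`DegenerateMaskError` if no pixel is true.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse paletted/RGB masks
        arr = arr[..., :3].max(axis=-1)
    mask = _scale_to_unit(arr) > threshold
    if not mask.any():
        raise DegenerateMaskError(f"{path}: mask has no true pixel")
    return mask


def write_segmentation(seg, path: str | Path) -> None:
    """Write a binary vessel map as an 8-bit PNG (vessels 255, background 0)."""
    binary = getattr(seg, "binary", seg)
    binary = check_binary(binary, "segmentation")
    path = Path(path)
    iio.imwrite(path, (binary.astype(np.uint8) * 255), extension=".png")


_NEIGHBOR_KERNEL = np.ones((3, 3), dtype=np.float64)


def extend_border_outside_fov(channel: np.ndarray, fov: np.ndarray,
                              iterations: int = 30) -> np.ndarray:
    """Continue the image smoothly outside the field of view.

    Pixels inside the FOV are untouched.  Outside pixels within
    ``iterations`` dilation steps of the FOV boundary are filled with the
    mean of their already-valid 8-neighbors, one dilation ring at a time.
    Any exterior pixels still unfilled are set to the mean intensity of the
    FOV boundary ring.
    """
    channel = as_float_image(channel)
    fov = check_binary(fov, "fov")
    if channel.shape != fov.shape:
        raise ValueError("channel and FOV dimensions differ")
    if not fov.any():
        raise DegenerateMaskError("FOV mask has no true pixel")

    out = channel.copy()
    valid = fov.copy()
    for _ in range(int(iterations)):
        frontier = ndimage.binary_dilation(valid, structure=_NEIGHBOR_KERNEL.astype(bool)) & ~valid
        if not frontier.any():
            break
        vf = valid.astype(np.float64)
        sums = ndimage.convolve(out * vf, _NEIGHBOR_KERNEL, mode="constant")
        counts = ndimage.convolve(vf, _NEIGHBOR_KERNEL, mode="constant")
        rows, cols = np.nonzero(frontier)
        out[rows, cols] = sums[rows, cols] / counts[rows, cols]
        valid |= frontier

    remaining = ~valid
    if remaining.any():
        boundary = fov & ~ndimage.binary_erosion(fov, structure=_NEIGHBOR_KERNEL.astype(bool))
        if not boundary.any():  # FOV of isolated pixels
            boundary = fov
        out[remaining] = channel[boundary].mean()
    return np.clip(out, 0.0, 1.0)


def estimate_fov_mask(image: ColorFundusImage, fraction: float = 0.12) -> np.ndarray:
    """Estimate a circular aperture mask when none ships with the image.

    Thresholds the channel-sum luminance at ``fraction`` of its maximum,
    keeps the largest connected component and fills its holes.
    """
    lum = image.red + image.green + image.blue
    rough = lum > fraction * lum.max()
    if not rough.any():
        raise DegenerateMaskError("luminance threshold left no FOV pixel")
    labels, n = ndimage.label(rough)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        rough = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(rough)
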