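"""Illumination correction, adaptive denoising and channel selection.

Homomorphic filtering treats a fundus photograph as the product of a
slowly varying illumination field and a high-frequency reflectance field:
taking the logarithm turns the product into a sum, a Gaussian high-pass
transfer function attenuates the illumination term (gain gamma_low at DC)
while passing reflectance (gain approaching gamma_high), and exponentiating
returns to intensity units.

The adaptive (local minimum-MSE) Wiener filter then shrinks each pixel
toward its local mean with gain (sigma^2 - v)/sigma^2, clamped to [0,1]:
strong smoothing in flat regions whose variance is at the noise floor v,
negligible smoothing on edges and vessels where sigma^2 >> v.

Finally the working channel is picked by contrast-to-noise ratio; in
fundus photographs this is normally the green channel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import as_float_image, check_binary, rescale_unit
from .exceptions import ParameterError

__all__ = [
    "HomomorphicParams",
    "WienerParams",
    "ChannelSelection",
    "gaussian_highpass_transfer",
    "homomorphic_filter",
    "local_mean",
    "local_variance",
    "adaptive_wiener",
    "select_best_channel",
]


@dataclass(frozen=True)
class HomomorphicParams:
    """Gaussian high-pass homomorphic transfer parameters.

    gamma_high / gamma_low are the asymptotic high- and low-frequency
    gains; d0 is the cutoff in frequency-bin distance from the centered DC
    term; epsilon guards the logarithm at zero intensity.
    """

    gamma_high: float = 1.8
    gamma_low: float = 0.4
    d0: float = 10.0
    epsilon: float = 0.01

    def __post_init__(self):
        if not (self.gamma_high > self.gamma_low > 0):
            raise ParameterError("require gamma_high > gamma_low > 0")
        if self.d0 <= 0:
            raise ParameterError("d0 must be positive")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")


@dataclass(frozen=True)
class WienerParams:
    """Local window and noise variance for the adaptive Wiener filter.

    noise_variance may be a number (intensity^2) or the string "estimate",
    in which case the mean of the local-variance map over the FOV is used.
    """

    window_rows: int = 3
    window_cols: int = 3
    noise_variance: float | str = "estimate"

    def __post_init__(self):
        for n in (self.window_rows, self.window_cols):
            if n < 3 or n % 2 == 0:
                raise ParameterError("Wiener window dimensions must be odd and >= 3")
        if not isinstance(self.noise_variance, str) and self.noise_variance < 0:
            raise ParameterError("noise_variance must be >= 0")
        if isinstance(self.noise_variance, str) and self.noise_variance != "estimate":
            raise ParameterError("noise_variance must be a number or 'estimate'")


@dataclass(frozen=True)
class ChannelSelection:
    chosen: str
    contrast_to_noise: dict = field(default_factory=dict)
    tie_break_order: tuple = ("green", "red", "blue")


def gaussian_highpass_transfer(dist, p: HomomorphicParams):
    """Transfer gain at frequency-plane distance ``dist`` from DC.

    (gamma_high - gamma_low) * (1 - exp(-dist^2/d0^2)) + gamma_low:
    monotone non-decreasing in dist, range [gamma_low, gamma_high).
    """
    dist = np.asarray(dist, dtype=np.float64)
    if np.any(dist < 0):
        raise ParameterError("frequency distance must be >= 0")
    out = (p.gamma_high - p.gamma_low) * (1.0 - np.exp(-(dist ** 2) / p.d0 ** 2)) + p.gamma_low
    return out if out.ndim else float(out)


def _frequency_distance(shape: tuple[int, int]) -> np.ndarray:
    # Euclidean distance, in frequency bins, to the DC bin after a centering
    # shift: fftfreq(n)*n gives signed bin indices on the unshifted grid, so
    # the distance map needs no explicit fftshift.
    fr = np.fft.fftfreq(shape[0]) * shape[0]
    fc = np.fft.fftfreq(shape[1]) * shape[1]
    return np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2)


def homomorphic_filter(f: np.ndarray, fov: np.ndarray,
                       p: HomomorphicParams = HomomorphicParams(),
                       rescale: bool = True) -> np.ndarray:
    """Suppress smooth illumination, keep reflectance.

    The input should already be continued outside the FOV (border
    extension) so the transform sees no hard aperture edge.  By default
    the output is min-max rescaled to [0,1] over the FOV for the next
    pipeline stage; ``rescale=False`` returns the raw exp-filtered image,
    on which the filter's physical effect (illumination attenuation) can
    be measured without the affine presentation step.
    """
    f = as_float_image(f)
    fov = check_binary(fov, "fov")
    log_img = np.log(f + p.epsilon)
    spectrum = np.fft.fft2(log_img)
    transfer = gaussian_highpass_transfer(_frequency_distance(f.shape), p)
    filtered = np.real(np.fft.ifft2(transfer * spectrum))
    out = np.exp(filtered) - p.epsilon
    if not rescale:
        return out
    return rescale_unit(out, fov, degenerate="keep")


def _uniform(f: np.ndarray, w: WienerParams) -> np.ndarray:
    return ndimage.uniform_filter(f, size=(w.window_rows, w.window_cols), mode="reflect")


def local_mean(f: np.ndarray, w: WienerParams = WienerParams()) -> np.ndarray:
    """Per-pixel mean over the N x M neighborhood, reflect-padded."""
    return _uniform(as_float_image(f), w)


def local_variance(f: np.ndarray, w: WienerParams = WienerParams()) -> np.ndarray:
    """Per-pixel E[I^2] - mu^2 over the neighborhood, clamped at 0."""
    f = as_float_image(f)
    mu = _uniform(f, w)
    return np.maximum(_uniform(f * f, w) - mu * mu, 0.0)


def adaptive_wiener(f: np.ndarray, w: WienerParams = WienerParams(),
                    fov: np.ndarray | None = None) -> np.ndarray:
    """Locally tuned minimum-MSE smoother.

    F = mu + (max(sigma^2 - v, 0)/sigma^2) * (I - mu); the gain is 0 where
    the local variance vanishes.  With noise_variance="estimate", v is the
    mean of the local-variance map over the FOV (whole frame if no FOV).
    """
    f = as_float_image(f)
    mu = local_mean(f, w)
    var = local_variance(f, w)
    if isinstance(w.noise_variance, str):
        sel = var if fov is None else var[check_binary(fov, "fov")]
        v = float(sel.mean())
    else:
        v = float(w.noise_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(var > 0, np.clip((var - v) / var, 0.0, 1.0), 0.0)
    return mu + gain * (f - mu)


_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


def _laplacian_noise_scale(f: np.ndarray, fov: np.ndarray) -> float:
    """Robust noise sigma: 1.4826 * MAD of the 4-neighbor Laplacian / sqrt(20).

    sqrt(20) is the L2 norm of the Laplacian stencil coefficients, so the
    estimate is on the scale of per-pixel noise; the median absolute
    deviation ignores the sparse vessel edges.
    """
    lap = ndimage.convolve(f, _LAPLACIAN, mode="reflect")[fov]
    mad = float(np.median(np.abs(lap - np.median(lap))))
    return 1.4826 * mad / np.sqrt(20.0)


def select_best_channel(processed, fov: np.ndarray) -> ChannelSelection:
    """Pick the channel maximizing contrast-to-noise over the FOV.

    CNR = std of FOV intensities / robust Laplacian noise scale.  Ties (and
    an all-zero noise estimate in every channel) resolve by the fixed order
    green > red > blue.
    """
    fov = check_binary(fov, "fov")
    order = ("green", "red", "blue")
    cnr: dict[str, float] = {}
    for name, ch in processed.channels().items():
        contrast = float(ch[fov].std())
        noise = _laplacian_noise_scale(ch, fov)
        if noise > 0:
            cnr[name] = contrast / noise
        else:  # noiseless: any structure wins, a constant channel never does
            cnr[name] = np.inf if contrast > 0 else 0.0
    best = order[0]
    for name in order[1:]:
        if cnr[name] > cnr[best]:
            best = name
    return ChannelSelection(chosen=best, contrast_to_noise=cnr)
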