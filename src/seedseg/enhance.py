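"""Multi-scale retinex with color restoration (MSRCR) scene enhancement.

The first stage of the pipeline: raw seed photographs are taken on a dark
background under uneven illumination, and MSRCR flattens the illumination
field while boosting local contrast, so that a single global threshold can
separate seeds from background afterwards.

For each channel :math:`I_i` the single-scale retinex response at surround
scale :math:`\\sigma_n` is

.. math:: R_{n,i} = \\log(I_i + 1) - \\log(G_{\\sigma_n} * I_i + 1)

where :math:`G_{\\sigma_n}` is a unit-sum Gaussian. The multi-scale response
is the weighted sum over scales, multiplied by the color-restoration factor

.. math:: C_i = \\beta\\,[\\log(\\alpha I_i + 1) - \\log(I_R + I_G + I_B + 1)]

and finally mapped linearly to 0–255 by clipping at configurable low/high
percentiles of the response ("simplest color balance").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from numpy.typing import NDArray
from scipy.signal import fftconvolve

from .errors import FormatError, ParameterError

__all__ = [
    "RetinexParams",
    "gaussian_surround",
    "msrcr",
    "read_scene",
    "write_scene",
]


@dataclass(frozen=True)
class RetinexParams:
    """MSRCR parameters.

    Defaults are the canonical values from the retinex literature: surround
    scales 15/80/250 px with equal weights, color restoration alpha=125,
    beta=46, and a 1%/99% percentile stretch.
    """

    scales: tuple[float, ...] = (15.0, 80.0, 250.0)
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    alpha: float = 125.0
    beta: float = 46.0
    stretch_low: float = 0.01
    stretch_high: float = 0.99
    #: percentiles computed per channel (default) or jointly over all channels
    per_channel_stretch: bool = True

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ParameterError("scales must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ParameterError("all surround scales must be > 0")
        if len(self.weights) != len(self.scales):
            raise ParameterError("weights must have the same length as scales")
        if any(w < 0 for w in self.weights):
            raise ParameterError("weights must be non-negative")
        if not math.isclose(sum(self.weights), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ParameterError("weights must sum to 1")
        if not (0.0 <= self.stretch_low < self.stretch_high <= 1.0):
            raise ParameterError("need 0 <= stretch_low < stretch_high <= 1")


def _gaussian_kernel(sigma: float) -> NDArray[np.float64]:
    """Unit-sum 1-D Gaussian sampled on integers, truncated at 3*sigma."""
    radius = max(1, int(math.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_surround(channel: NDArray, sigma: float) -> NDArray[np.float64]:
    """Convolve one channel with a normalized Gaussian surround.

    The kernel is truncated at 3*sigma and edges are handled by reflection,
    so constants are preserved exactly and no dark halo appears at borders.
    Implemented as a separable FFT convolution on a reflect-padded copy;
    at the 250 px scales used on megapixel scenes a direct spatial
    convolution would be orders of magnitude slower.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2 or channel.size == 0:
        raise FormatError("channel must be a non-empty 2-D array")
    k = _gaussian_kernel(sigma)
    r = (len(k) - 1) // 2
    padded = np.pad(channel, r, mode="reflect")
    out = fftconvolve(padded, k[:, None], mode="same")
    out = fftconvolve(out, k[None, :], mode="same")
    return out[r:-r, r:-r]


def _stretch_channel(ch: NDArray[np.float64], lo: float, hi: float) -> NDArray[np.float64]:
    """Linear map of [q_lo, q_hi] quantiles to [0, 255], clipped."""
    p_lo, p_hi = np.quantile(ch, [lo, hi])
    if p_hi - p_lo < 1e-12:
        # flat response (e.g. constant input): no contrast to restore
        return np.full_like(ch, 127.0)
    return np.clip((ch - p_lo) / (p_hi - p_lo), 0.0, 1.0) * 255.0


def msrcr(scene: NDArray[np.uint8], params: RetinexParams | None = None) -> NDArray[np.uint8]:
    """Enhance an 8-bit RGB scene with multi-scale retinex + color restoration.

    Returns a same-shape 8-bit RGB image. Constant scenes map to constant
    scenes (the retinex response is identically zero before range
    restoration).
    """
    params = params or RetinexParams()
    scene = np.asarray(scene)
    if scene.ndim != 3 or scene.shape[2] != 3:
        raise FormatError(f"expected an HxWx3 RGB scene, got shape {scene.shape}")
    img = scene.astype(np.float64)

    log_img = np.log(img + 1.0)
    retinex = np.zeros_like(img)
    for sigma, w in zip(params.scales, params.weights):
        for c in range(3):
            surround = gaussian_surround(img[:, :, c], sigma)
            retinex[:, :, c] += w * (log_img[:, :, c] - np.log(surround + 1.0))

    channel_sum = img.sum(axis=2)
    restoration = params.beta * (
        np.log(params.alpha * img + 1.0) - np.log(channel_sum + 1.0)[:, :, None]
    )
    response = restoration * retinex

    out = np.empty_like(response)
    if params.per_channel_stretch:
        for c in range(3):
            out[:, :, c] = _stretch_channel(
                response[:, :, c], params.stretch_low, params.stretch_high
            )
    else:
        p_lo, p_hi = np.quantile(response, [params.stretch_low, params.stretch_high])
        if p_hi - p_lo < 1e-12:
            out[:] = 127.0
        else:
            out = np.clip((response - p_lo) / (p_hi - p_lo), 0.0, 1.0) * 255.0
    return np.rint(out).astype(np.uint8)


def read_scene(path) -> NDArray[np.uint8]:
    """Read a BMP/JPG/PNG scene as an 8-bit RGB array (alpha dropped)."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"cannot interpret {path} as an RGB scene")
    return np.ascontiguousarray(img, dtype=np.uint8)


def write_scene(path, scene: NDArray[np.uint8]) -> None:
    """Write an 8-bit RGB scene; format chosen from the file extension."""
    iio.imwrite(path, np.asarray(scene, dtype=np.uint8))
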