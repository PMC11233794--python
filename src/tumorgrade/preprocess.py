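"""Phase-1 preprocessing: nearest-neighbor resizing and pixel-wise adaptive Wiener denoising.

Every MRI image is first brought to a common size (600x600 by convention)
with nearest-neighbor interpolation, then denoised with the two-dimensional
adaptive Wiener filter, which estimates a local mean and variance in an
N-by-M neighborhood of each pixel and shrinks the pixel toward its local
mean in proportion to how much of the local variance is attributable to
noise.

All arithmetic is carried out on float64 arrays; quantization back to the
0-255 range happens only when an image is written to disk (see
:mod:`tumorgrade.imageio`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "WienerParams",
    "LocalStats",
    "WienerResult",
    "resize_nearest",
    "decimate_halve",
    "local_stats",
    "wiener_filter",
]

#: Guard against division by a vanishing local variance.
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class WienerParams:
    """Neighborhood shape and (optional) noise variance for the Wiener filter.

    Parameters
    ----------
    window_height, window_width:
        Odd neighborhood dimensions N and M, in pixels.
    noise_variance:
        The noise power nu^2 in squared intensity units.  When ``None`` the
        filter uses the average of all local variance estimates, the
        standard behavior of the two-dimensional adaptive filter.
    """

    window_height: int = 3
    window_width: int = 3
    noise_variance: float | None = None

    def __post_init__(self) -> None:
        for n in (self.window_height, self.window_width):
            if n < 1 or n % 2 == 0:
                raise ValueError(f"window dimensions must be odd and positive, got {n}")
        if self.noise_variance is not None and self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


@dataclass(frozen=True)
class LocalStats:
    """Per-pixel neighborhood mean and variance maps."""

    mean: np.ndarray
    variance: np.ndarray


@dataclass(frozen=True)
class WienerResult:
    """Filtered image plus the noise variance the filter actually used."""

    image: np.ndarray
    noise_variance: float


def _as_float_image(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2-D grayscale image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def resize_nearest(img: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Resize to ``out_height x out_width`` by nearest-neighbor interpolation.

    The source index for output row ``i`` is ``floor((i + 0.5) * H_in / H_out)``
    (and likewise for columns), so an integer-factor upscale replicates each
    pixel into a k x k block and no new intensity values are ever created.
    """
    a = _as_float_image(img)
    if out_height < 1 or out_width < 1:
        raise ValueError("output dimensions must be positive")
    h, w = a.shape
    rows = np.minimum((np.floor((np.arange(out_height) + 0.5) * h / out_height)).astype(int), h - 1)
    cols = np.minimum((np.floor((np.arange(out_width) + 0.5) * w / out_width)).astype(int), w - 1)
    return a[np.ix_(rows, cols)]


def decimate_halve(img: np.ndarray) -> np.ndarray:
    """Halve both dimensions by removing every second row and column.

    Keeps the rows and columns with odd 1-based index (the 1st, 3rd, ...),
    so the output has exactly half the height and width.  Odd input
    dimensions are rejected because "every second" is then ambiguous.
    """
    a = _as_float_image(img)
    h, w = a.shape
    if h % 2 or w % 2:
        raise ValueError(f"decimate_halve requires even dimensions, got {a.shape}")
    return a[0::2, 0::2]


def local_stats(img: np.ndarray, params: WienerParams = WienerParams()) -> LocalStats:
    """Neighborhood mean and variance maps over an N x M window at each pixel.

    The mean is the window sum divided by the full N*M (zero padding outside
    the image), and the variance is the window mean of squares minus the
    squared mean, clamped at zero against floating-point round-off.
    """
    a = _as_float_image(img)
    n, m = params.window_height, params.window_width
    if n > 2 * a.shape[0] or m > 2 * a.shape[1]:
        raise ValueError(
            f"window {n}x{m} too large for image of shape {a.shape}"
        )
    size = (n, m)
    mean = ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0)
    mean_sq = ndimage.uniform_filter(a * a, size=size, mode="constant", cval=0.0)
    variance = np.maximum(mean_sq - mean * mean, 0.0)
    return LocalStats(mean=mean, variance=variance)


def wiener_filter(img: np.ndarray, params: WienerParams = WienerParams()) -> WienerResult:
    """Pixel-wise adaptive Wiener filter.

    Each pixel ``a`` is replaced by ``mu + (sigma^2 - nu^2)/sigma^2 * (a - mu)``
    using the local statistics of :func:`local_stats`.  Two degeneracies are
    guarded: ``sigma^2 - nu^2`` is clamped at zero (never amplify away from
    the mean), and pixels whose local variance is zero return the local mean.
    With ``noise_variance=0`` the filter is the identity.
    """
    a = _as_float_image(img)
    stats = local_stats(a, params)
    if params.noise_variance is None:
        nu2 = float(stats.variance.mean())
    else:
        nu2 = float(params.noise_variance)
    gain = np.maximum(stats.variance - nu2, 0.0) / np.maximum(stats.variance, _VAR_EPS)
    out = stats.mean + gain * (a - stats.mean)
    return WienerResult(image=out, noise_variance=nu2)
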