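"""Functional building blocks of the binary convolutional neural network.

The 1-bit quantization of the network lives in the two binarization
functions: the deterministic sign (zero maps to +1) and the stochastic
draw whose +1 probability is the hard sigmoid clip((x+1)/2, 0, 1).  The
remaining operations — cross-correlation, max pooling, min-max batch
normalization, the affine fully connected map and the stabilized softmax —
are ordinary dense float operations; only the *weights* fed into the
convolution are binary.

Spatial tensors are laid out H x W x D (or N x H x W x D batched), with the
channel axis last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "sign_binarize",
    "hard_sigmoid",
    "stochastic_binarize",
    "conv_forward",
    "conv_output_shape",
    "maxpool",
    "NormState",
    "minmax_normalize",
    "FCLayer",
    "fc_forward",
    "softmax",
    "softmax_predict",
]


def sign_binarize(x: np.ndarray | float) -> np.ndarray:
    """Deterministic binarization: +1 where x >= 0, -1 otherwise."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, 1.0, -1.0)


def hard_sigmoid(x: np.ndarray | float) -> np.ndarray:
    """Piecewise-linear sigmoid clip((x + 1)/2, 0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    return np.clip((x + 1.0) / 2.0, 0.0, 1.0)


def stochastic_binarize(x: np.ndarray, rng: np.random.Generator | int) -> np.ndarray:
    """Stochastic binarization: +1 with probability hard_sigmoid(x), else -1.

    ``rng`` may be a Generator or an integer seed; draws are independent
    per element and reproducible under a fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=np.float64)
    p = hard_sigmoid(x)
    return np.where(rng.random(x.shape) < p, 1.0, -1.0)


def conv_output_shape(h: int, w: int, kh: int, kw: int, stride: int, pad: int) -> tuple[int, int]:
    return ((h + 2 * pad - kh) // stride + 1, (w + 2 * pad - kw) // stride + 1)


def _conv_windows(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Sliding kh x kw windows of a padded N x H x W x D batch."""
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    if kh > xp.shape[1] or kw > xp.shape[2]:
        raise ValueError(
            f"kernel {kh}x{kw} larger than padded input {xp.shape[1]}x{xp.shape[2]}")
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    return win[:, ::stride, ::stride]  # (N, H3, W3, D, kh, kw)


def conv_forward(x: np.ndarray, kernels: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Valid cross-correlation of an H x W x D input with H2 x W2 x D1 x D2 kernels.

    Accepts a single image (H, W, D) or a batch (N, H, W, D); the output has
    spatial dimensions floor((H + 2*pad - H2)/stride) + 1 and depth D2.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"expected (N,)H x W x D input, got shape {x.shape}")
    kernels = np.asarray(kernels, dtype=np.float64)
    kh, kw, din, dout = kernels.shape
    if din != x.shape[3]:
        raise ValueError(f"kernel depth {din} does not match input depth {x.shape[3]}")
    if stride < 1 or pad < 0:
        raise ValueError("stride must be >= 1 and pad >= 0")
    win = _conv_windows(x, kh, kw, stride, pad)
    out = np.einsum("nhwdjk,jkdo->nhwo", win, kernels, optimize=True)
    return out[0] if single else out


def maxpool(x: np.ndarray, window: int = 2, stride: int = 2) -> np.ndarray:
    """Per-channel max pooling over non-overlapping windows.

    The pad-free preset requires ``window == stride`` and spatial dimensions
    divisible by the stride; the channel depth is unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 3
    if single:
        x = x[None]
    if window != stride:
        raise ValueError("pad-free max pooling requires window == stride")
    n, h, w, d = x.shape
    if window > h or window > w:
        raise ValueError(f"pool window {window} larger than input {h}x{w}")
    if h % stride or w % stride:
        raise ValueError(f"input {h}x{w} not divisible by stride {stride}")
    xr = x.reshape(n, h // window, window, w // window, window, d)
    out = xr.max(axis=(2, 4))
    return out[0] if single else out


@dataclass
class NormState:
    """Per-channel statistics of the min-max batch normalization.

    ``mean``, ``x_max`` and ``x_min`` hold the statistics of the current
    batch; the ``running_*`` copies are exponential moving averages
    (momentum 0.9) used at inference time.
    """

    mean: np.ndarray | None = None
    x_max: np.ndarray | None = None
    x_min: np.ndarray | None = None
    running_mean: np.ndarray | None = None
    running_max: np.ndarray | None = None
    running_min: np.ndarray | None = None
    momentum: float = 0.9

    def update(self, mean: np.ndarray, x_max: np.ndarray, x_min: np.ndarray) -> None:
        if np.any(x_max < x_min):
            raise ValueError("x_max must be >= x_min")
        self.mean, self.x_max, self.x_min = mean, x_max, x_min
        if self.running_mean is None:
            self.running_mean, self.running_max, self.running_min = mean, x_max, x_min
        else:
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_max = m * self.running_max + (1 - m) * x_max
            self.running_min = m * self.running_min + (1 - m) * x_min


def minmax_normalize(x: np.ndarray, state: NormState, training: bool = True,
                     mode: str = "meanrange") -> np.ndarray:
    """Range-scaled centering (x - m)/(x_max - x_min), per channel.

    The default ``meanrange`` mode centers on the mean m, which bounds the
    output in [-1, 1]; ``minmax01`` uses (x - x_min)/(x_max - x_min), which
    maps the batch onto [0, 1].  Channels with zero range map to zeros.
    In training mode the statistics come from the current batch and the
    running averages are updated; in inference mode the running statistics
    are used.
    """
    x = np.asarray(x, dtype=np.float64)
    if mode not in ("meanrange", "minmax01"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    axes = tuple(range(x.ndim - 1))
    if training or state.running_mean is None:
        mean = x.mean(axis=axes)
        x_max = x.max(axis=axes)
        x_min = x.min(axis=axes)
        if training:
            state.update(mean, x_max, x_min)
    else:
        mean, x_max, x_min = state.running_mean, state.running_max, state.running_min
    rng = x_max - x_min
    center = mean if mode == "meanrange" else x_min
    safe = np.where(rng > 0, rng, 1.0)
    out = (x - center) / safe
    return np.where(rng > 0, out, 0.0)


@dataclass
class FCLayer:
    """Fully connected layer y = g(w x + b)."""

    w: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.w.ndim != 2 or self.b.shape != (self.w.shape[0],):
            raise ValueError("weight matrix must be (outputs, inputs) with matching bias")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


def fc_forward(x: np.ndarray, layer: FCLayer) -> np.ndarray:
    """Affine map followed by the layer's activation; accepts (in,) or (N, in)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != layer.w.shape[1]:
        raise ValueError(
            f"input of size {x.shape[-1]} does not match weight matrix {layer.w.shape}")
    z = x @ layer.w.T + layer.b
    if layer.activation == "relu":
        return np.maximum(z, 0.0)
    return z


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax along the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_predict(logits: np.ndarray) -> tuple[np.ndarray, int]:
    """Class probabilities and the argmax label index (ties to the lowest index)."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 1:
        raise ValueError("softmax_predict expects a single logit vector")
    p = softmax(logits)
    return p, int(np.argmax(p))
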