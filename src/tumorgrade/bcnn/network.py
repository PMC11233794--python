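"""The binary CNN classifier: layer stack, training loop, checkpoints.

Architecture: three convolution blocks, each a binarized 7x7 convolution
(8 kernels, stride 1, "same" padding) followed by 2x2 max pooling and
min-max normalization, then a flatten and one fully connected layer
producing the five class logits (Grade I-IV, Healthy), trained with
softmax cross-entropy.

Only the convolution kernels are binarized: each conv layer keeps latent
real-valued weights, the forward pass uses their sign (or a stochastic
draw during training, if enabled), and gradients flow back to the latent
weights through a straight-through estimator clipped at |w| <= 1.  The
fully connected layer keeps real weights.

Training alternates two moves per epoch: a mini-batch SGD-with-momentum
pass through the whole stack (latent conv weights on a reduced step), then
an exact recalibration of the normalization statistics over the training
set followed by a near-complete solve of the convex linear-head subproblem
on the cached features (full-batch Adam with a ridge penalty).  Everything
is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..phantom import CLASSES
from ..preprocess import resize_nearest
from .ops import (
    FCLayer,
    NormState,
    _conv_windows,
    fc_forward,
    minmax_normalize,
    sign_binarize,
    softmax,
    stochastic_binarize,
)

__all__ = ["BCNNConfig", "EpochStats", "TrainReport", "BCNNModel", "train",
           "prepare_inputs", "save_model", "load_model"]


@dataclass(frozen=True)
class BCNNConfig:
    """Hyperparameters of the binary CNN preset.

    The paper-faithful preset has exactly three convolution blocks and one
    fully connected layer; counts, kernel sizes, the optimizer and the
    backward rule for the sign are preset knobs of this package.
    """

    input_side: int = 64
    n_blocks: int = 3
    channels: int = 8
    kernel: int = 7
    pad: int = 3
    init_positive_bias: float = 2.0
    binarization: str = "deterministic"  # or "stochastic" (training only)
    norm_mode: str = "meanrange"         # or "minmax01"
    learning_rate: float = 0.05
    momentum: float = 0.9
    conv_lr_scale: float = 0.02
    head_refine_steps: int = 600
    head_l2: float = 4e-4
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    stop_at_train_accuracy: float | None = 100.0
    stop_at_train_loss: float = 0.25

    def __post_init__(self) -> None:
        if self.input_side % (2 ** self.n_blocks):
            raise ValueError("input_side must be divisible by 2**n_blocks")
        if self.binarization not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown binarization mode {self.binarization!r}")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        if not (0 < self.learning_rate and 0 <= self.momentum < 1):
            raise ValueError("invalid optimizer parameters")


@dataclass(frozen=True)
class EpochStats:
    epoch: int
    train_accuracy: float  # percent
    train_loss: float


@dataclass
class TrainReport:
    epochs: list[EpochStats]
    final_train_accuracy: float
    final_train_loss: float
    seed: int
    config: BCNNConfig

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(e) for e in self.epochs])


class _BinConv:
    """Binarized convolution layer with latent real kernels (stride 1)."""

    def __init__(self, kernel: int, din: int, dout: int, pad: int,
                 rng: np.random.Generator, positive_bias: float = 0.0,
                 need_dx: bool = True):
        fan_in = kernel * kernel * din
        fan_out = kernel * kernel * dout
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        # positive_bias shifts the latent distribution toward +1 signs: on
        # {-1,+1} mask inputs all-plus kernels act as local
        # foreground-occupancy counters, a size-sensitive feature basis
        # that training then refines (bias >= 1 starts every sign at +1
        # while keeping the latent magnitudes diverse)
        self.latent = (rng.uniform(-limit, limit, size=(kernel, kernel, din, dout))
                       + positive_bias * limit)
        self.pad = pad
        self.need_dx = need_dx  # the first layer can skip its input gradient
        self._cache: dict | None = None

    def binarized(self, training: bool, mode: str,
                  rng: np.random.Generator | None) -> np.ndarray:
        if training and mode == "stochastic":
            assert rng is not None
            return stochastic_binarize(self.latent, rng)
        return sign_binarize(self.latent)

    def forward(self, x: np.ndarray, training: bool, mode: str,
                rng: np.random.Generator | None) -> np.ndarray:
        wb = self.binarized(training, mode, rng)
        kh, kw, din, dout = wb.shape
        win = _conv_windows(x, kh, kw, stride=1, pad=self.pad)
        n, h, w = win.shape[:3]
        # im2col + GEMM: contiguous copy of the window view, one matmul
        col = np.ascontiguousarray(win).reshape(n * h * w, din * kh * kw)
        wmat = wb.transpose(2, 0, 1, 3).reshape(din * kh * kw, dout)
        out = (col @ wmat).reshape(n, h, w, dout)
        if training:
            self._cache = {"col": col, "wb": wb, "xshape": x.shape,
                           "oshape": (n, h, w)}
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache = self._cache
        assert cache is not None
        col, wb = cache["col"], cache["wb"]
        kh, kw, din, dout = wb.shape
        dymat = dy.reshape(-1, dout)
        dwb = (col.T @ dymat).reshape(din, kh, kw, dout).transpose(1, 2, 0, 3)
        # straight-through estimator: pass the gradient of the binarized
        # weight to the latent weight, zeroed where |latent| > 1
        self.grad = dwb * (np.abs(self.latent) <= 1.0)
        if not self.need_dx:
            return None
        # gradient w.r.t. the input: full correlation with flipped kernels
        n, h, w, _ = cache["xshape"]
        dyp = np.pad(dy, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
        winy = np.lib.stride_tricks.sliding_window_view(dyp, (kh, kw), axis=(1, 2))
        ny, hy, wy = winy.shape[:3]
        coly = np.ascontiguousarray(winy).reshape(ny * hy * wy, dout * kh * kw)
        # dxp[.., d] = sum_{j,k,o} dyp[.. + j, .. + k, o] * wb[kh-1-j, kw-1-k, d, o]
        wflip = wb[::-1, ::-1].transpose(3, 0, 1, 2).reshape(dout * kh * kw, din)
        dxp = (coly @ wflip).reshape(ny, hy, wy, din)
        p = self.pad
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [("latent", self)]


class _MaxPool:
    def __init__(self, window: int = 2):
        self.window = window
        self._cache = None

    def forward(self, x: np.ndarray, training: bool, *_args) -> np.ndarray:
        k = self.window
        n, h, w, d = x.shape
        if h % k or w % k:
            raise ValueError(f"input {h}x{w} not divisible by pool window {k}")
        xr = x.reshape(n, h // k, k, w // k, k, d)
        flat = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // k, w // k, k * k, d)
        idx = flat.argmax(axis=3)
        out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._cache = (idx, (n, h, w, d))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, d) = self._cache
        k = self.window
        flat = np.zeros((n, h // k, w // k, k * k, d))
        np.put_along_axis(flat, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        xr = flat.reshape(n, h // k, w // k, k, k, d).transpose(0, 1, 3, 2, 4, 5)
        return xr.reshape(n, h, w, d)

    def params(self):
        return []


class _MinMaxNorm:
    def __init__(self, mode: str = "meanrange"):
        self.state = NormState()
        self.mode = mode
        self._cache = None

    def forward(self, x: np.ndarray, training: bool, *_args) -> np.ndarray:
        # the statistics m, x_max, x_min are dataset-level quantities
        # (the mean/extrema of the data set), held fixed within an epoch
        # and recomputed by calibrate(); until the first calibration pass
        # they are estimated from the first batch seen
        if self.state.running_mean is None:
            axes = tuple(range(x.ndim - 1))
            self.state.running_mean = x.mean(axis=axes)
            self.state.running_max = x.max(axis=axes)
            self.state.running_min = x.min(axis=axes)
        out = minmax_normalize(x, self.state, training=False, mode=self.mode)
        if training:
            rng = (self.state.running_max - self.state.running_min)
            self._cache = np.where(rng > 0, rng, np.inf)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # the dataset statistics are constants of the forward pass
        return dy / self._cache

    def params(self):
        return []

    def calibrate_forward(self, x: np.ndarray) -> np.ndarray:
        """Set the inference statistics from a full-dataset pass.

        Per-batch extrema are noisy estimates of the dataset extrema (the
        expected batch maximum is biased low, and the running average lags
        behind the moving features), so after training the statistics are
        recomputed exactly over the whole training set, the analogue of
        precise batch-norm recalibration.
        """
        axes = tuple(range(x.ndim - 1))
        self.state.running_mean = x.mean(axis=axes)
        self.state.running_max = x.max(axis=axes)
        self.state.running_min = x.min(axis=axes)
        return minmax_normalize(x, self.state, training=False, mode=self.mode)


class _Flatten:
    def forward(self, x: np.ndarray, training: bool, *_args) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    """Real-valued fully connected layer (the final classifier head)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.layer = FCLayer(w=rng.uniform(-limit, limit, size=(n_out, n_in)),
                             b=np.zeros(n_out), activation="identity")
        self._cache = None

    def forward(self, x: np.ndarray, training: bool, *_args) -> np.ndarray:
        if training:
            self._cache = x
        return fc_forward(x, self.layer)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grad_w = dy.T @ x
        self.grad_b = dy.sum(axis=0)
        return dy @ self.layer.w

    def params(self):
        return [("w", self), ("b", self)]


class BCNNModel:
    """Trained (or freshly initialized) binary CNN over 5 grade classes."""

    def __init__(self, config: BCNNConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        self.layers: list = []
        din = 1
        for _ in range(config.n_blocks):
            self.layers.append(_BinConv(config.kernel, din, config.channels,
                                        config.pad, rng,
                                        positive_bias=config.init_positive_bias,
                                        need_dx=len(self.layers) > 0))
            self.layers.append(_MaxPool(2))
            self.layers.append(_MinMaxNorm(config.norm_mode))
            din = config.channels
        side = config.input_side
        out_side = side
        for _ in range(config.n_blocks):
            out_side = (out_side + 2 * config.pad - config.kernel) + 1
            out_side //= 2
        self.layers.append(_Flatten())
        self.layers.append(_Dense(out_side * out_side * config.channels,
                                  len(CLASSES), rng))

    # -- forward ---------------------------------------------------------
    def logits(self, x: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        mode = self.config.binarization
        out = x
        for layer in self.layers:
            out = layer.forward(out, training, mode, rng)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, training=False))

    def predict_indices(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        preds = []
        for i in range(0, x.shape[0], batch_size):
            preds.append(np.argmax(self.logits(x[i:i + batch_size]), axis=1))
        return np.concatenate(preds)

    def predict_labels(self, x: np.ndarray) -> list[str]:
        return [CLASSES[i] for i in self.predict_indices(x)]

    def features(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode activations entering the fully connected layer."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            out = x[i:i + batch_size]
            for layer in self.layers[:-1]:
                out = layer.forward(out, False, self.config.binarization, None)
            outs.append(out)
        return np.concatenate(outs)

    def calibrate(self, x: np.ndarray) -> None:
        """Recompute the normalization statistics exactly over ``x``.

        Runs one inference-mode pass (deterministic sign weights, no
        gradient caches) in which every normalization layer replaces its
        running statistics with the exact per-channel mean/max/min of the
        full set — the analogue of precise batch-norm recalibration.
        """
        out = x
        for layer in self.layers:
            if isinstance(layer, _MinMaxNorm):
                out = layer.calibrate_forward(out)
            else:
                out = layer.forward(out, False, self.config.binarization, None)

    def conv_layers(self) -> list[_BinConv]:
        return [l for l in self.layers if isinstance(l, _BinConv)]

    def dense(self) -> _Dense:
        return self.layers[-1]


def prepare_inputs(masks: list[np.ndarray] | np.ndarray, side: int) -> np.ndarray:
    """Resize binary masks to ``side x side`` and map {0,1} to {-1,+1}.

    Nearest-neighbor resizing never creates new values, so the result is
    exactly binary in {-1, +1}, shaped (N, side, side, 1).
    """
    out = np.empty((len(masks), side, side, 1))
    for i, m in enumerate(masks):
        r = resize_nearest(np.asarray(m, dtype=np.float64), side, side)
        out[i, :, :, 0] = 2.0 * r - 1.0
    return out


def _labels_to_indices(labels: list[str]) -> np.ndarray:
    try:
        return np.array([CLASSES.index(l) for l in labels])
    except ValueError as e:
        raise ValueError(f"labels must be drawn from {CLASSES}") from e


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def train(config: BCNNConfig, masks: list[np.ndarray],
          labels: list[str]) -> tuple[BCNNModel, TrainReport]:
    """Train the binary CNN on labeled binary masks.

    Per epoch the training set is shuffled and consumed in mini-batches;
    after each epoch, accuracy and loss over the full training set are
    recorded in inference mode (deterministic sign weights, running
    normalization statistics).  Training stops early once the accuracy
    reaches ``stop_at_train_accuracy``.  Fixed seed implies a
    bit-reproducible model and report.
    """
    if len(masks) == 0:
        raise ValueError("training set is empty")
    y = _labels_to_indices(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two distinct classes")
    x = prepare_inputs(masks, config.input_side)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 7]))
    model = BCNNModel(config, rng=np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 11])))

    velocity: dict[tuple[int, str], np.ndarray] = {}
    history: list[EpochStats] = []
    n = len(y)
    model.calibrate(x)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.logits(xb, training=True, rng=rng)
            probs = softmax(logits)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grad = dlogits
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            _sgd_step(model, velocity, config.learning_rate, config.momentum,
                      config.conv_lr_scale)
        model.calibrate(x)
        feats = model.features(x)
        if config.head_refine_steps:
            _refine_head(model.dense(), feats, y, config.head_refine_steps,
                         l2=config.head_l2)
        acc, loss = _head_metrics(model.dense(), feats, y)
        history.append(EpochStats(epoch=epoch, train_accuracy=acc, train_loss=loss))
        # stop only once the training set is both fully fit and fit with
        # margin (small loss): accuracy alone can be reached with logits
        # barely past the decision boundary, which generalizes poorly
        if (config.stop_at_train_accuracy is not None
                and acc >= config.stop_at_train_accuracy
                and loss <= config.stop_at_train_loss):
            break
    report = TrainReport(epochs=history,
                         final_train_accuracy=history[-1].train_accuracy,
                         final_train_loss=history[-1].train_loss,
                         seed=config.seed, config=config)
    return model, report


def _refine_head(dense: "_Dense", feats: np.ndarray, y: np.ndarray,
                 steps: int, lr: float = 0.05, l2: float = 0.0) -> None:
    """Solve the linear-head subproblem on the current (frozen) features.

    One joint mini-batch pass per epoch moves the binarized convolutions
    slowly, but leaves the convex softmax-regression problem of the final
    layer far from its optimum.  Because the features entering the head are
    already computed, full-batch gradient steps on the head alone cost
    almost nothing, so each epoch ends by fitting the head to
    near-convergence with Adam on the cached features (deterministic; no
    randomness involved).
    """
    w, b = dense.layer.w, dense.layer.b
    mw = np.zeros_like(w); vw = np.zeros_like(w)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    n = len(y)
    for t in range(1, steps + 1):
        probs = softmax(feats @ w.T + b)
        d = probs
        d[np.arange(n), y] -= 1.0
        d /= n
        gw = d.T @ feats + l2 * w  # ridge penalty on the weights only
        gb = d.sum(axis=0)
        for g, m_, v_, p_ in ((gw, mw, vw, w), (gb, mb, vb, b)):
            m_ *= 0.9; m_ += 0.1 * g
            v_ *= 0.999; v_ += 0.001 * g * g
            p_ -= lr * (m_ / (1 - 0.9 ** t)) / (np.sqrt(v_ / (1 - 0.999 ** t)) + 1e-8)


def _head_metrics(dense: "_Dense", feats: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = softmax(feats @ dense.layer.w.T + dense.layer.b)
    acc = 100.0 * float(np.mean(np.argmax(probs, axis=1) == y))
    return acc, _cross_entropy(probs, y)


def _sgd_step(model: BCNNModel, velocity: dict, lr: float, momentum: float,
              conv_lr_scale: float = 1.0) -> None:
    # latent conv weights move on a smaller step: a sign flip changes the
    # forward network discontinuously, so the 1-bit layers are refined
    # slowly while the real-valued head is fit at the full rate
    for li, layer in enumerate(model.layers):
        if isinstance(layer, _BinConv):
            v = velocity.setdefault((li, "latent"), np.zeros_like(layer.latent))
            v *= momentum
            v -= lr * conv_lr_scale * layer.grad
            layer.latent += v
        elif isinstance(layer, _Dense):
            vw = velocity.setdefault((li, "w"), np.zeros_like(layer.layer.w))
            vb = velocity.setdefault((li, "b"), np.zeros_like(layer.layer.b))
            vw *= momentum
            vw -= lr * layer.grad_w
            vb *= momentum
            vb -= lr * layer.grad_b
            layer.layer.w += vw
            layer.layer.b += vb


def _train_metrics(model: BCNNModel, x: np.ndarray, y: np.ndarray,
                   batch_size: int) -> tuple[float, float]:
    correct = 0
    losses = []
    for i in range(0, len(y), batch_size):
        probs = softmax(model.logits(x[i:i + batch_size]))
        pred = np.argmax(probs, axis=1)
        correct += int((pred == y[i:i + batch_size]).sum())
        losses.append(_cross_entropy(probs, y[i:i + batch_size]) * len(pred))
    return 100.0 * correct / len(y), float(np.sum(losses) / len(y))


# -- checkpointing -------------------------------------------------------

def save_model(model: BCNNModel, path: str | Path) -> None:
    """Serialize latent weights, running norm statistics and config (.npz)."""
    arrays: dict[str, np.ndarray] = {}
    for i, conv in enumerate(model.conv_layers()):
        arrays[f"conv{i}_latent"] = conv.latent
    for i, layer in enumerate(model.layers):
        if isinstance(layer, _MinMaxNorm) and layer.state.running_mean is not None:
            arrays[f"norm{i}_mean"] = layer.state.running_mean
            arrays[f"norm{i}_max"] = layer.state.running_max
            arrays[f"norm{i}_min"] = layer.state.running_min
    dense = model.dense()
    arrays["dense_w"] = dense.layer.w
    arrays["dense_b"] = dense.layer.b
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> BCNNModel:
    with np.load(path) as data:
        config = BCNNConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = BCNNModel(config)
        for i, conv in enumerate(model.conv_layers()):
            conv.latent = data[f"conv{i}_latent"]
        for i, layer in enumerate(model.layers):
            if isinstance(layer, _MinMaxNorm) and f"norm{i}_mean" in data:
                layer.state.running_mean = data[f"norm{i}_mean"]
                layer.state.running_max = data[f"norm{i}_max"]
                layer.state.running_min = data[f"norm{i}_min"]
        dense = model.dense()
        dense.layer.w = data["dense_w"]
        dense.layer.b = data["dense_b"]
    return model
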