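"""Minimal NumPy neural-network engine for DAG-structured CNNs.

Implements exactly the layer set SWNet needs — 3x3 convolution, batch
normalization, ReLU, channel concatenation, global average pooling, fully
connected, dropout and softmax — each with a hand-written backward pass, plus
mini-batch SGD with momentum.

Activations are channels-last, ``(N, H, W, C)``.  Convolutions use the
shift-and-matmul formulation: the 3x3 kernel is applied as nine shifted
slices of the padded input, each multiplied by a (C_in, C_out) weight slab,
so the inner loops are BLAS matmuls over contiguous channel vectors and no
im2col buffer is materialized.  The backward pass mirrors this with nine
strided scatter-adds, which stay fully vectorized.

All layers keep their parameters in a ``params`` dict and deposit matching
``grads`` during ``backward``; a graph executor (see :mod:`swnet.arch`)
wires layers together and handles fan-out/fan-in gradient accumulation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dense",
    "Dropout",
    "he_normal",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    """He/Kaiming fan-in normal initialization, suited to ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d:
    """3×3 convolution with bias, same-padding 1, stride 1 or 2.

    Weights are stored as ``(3, 3, C_in, C_out)`` so each kernel tap is a
    matmul-ready slab.
    """

    kind = "conv"

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 *, rng: np.random.Generator | None = None, dtype=np.float32):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params = {
            "W": he_normal(rng, (3, 3, in_channels, out_channels),
                           9 * in_channels, dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        s = self.stride
        oh, ow = h // s, w // s
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        W = self.params["W"]
        y = np.empty((n * oh * ow, self.out_channels), dtype=x.dtype)
        y[:] = self.params["b"]
        span_h, span_w = (oh - 1) * s + 1, (ow - 1) * s + 1
        for i in range(3):
            for j in range(3):
                xs = xp[:, i:i + span_h:s, j:j + span_w:s, :]
                y += xs.reshape(-1, c) @ W[i, j]
        self._cache = (xp, (h, w))
        return y.reshape(n, oh, ow, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (h, w) = self._cache
        n, oh, ow, cout = dy.shape
        s = self.stride
        c = self.in_channels
        dyf = dy.reshape(-1, cout)
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        span_h, span_w = (oh - 1) * s + 1, (ow - 1) * s + 1
        for i in range(3):
            for j in range(3):
                xs = xp[:, i:i + span_h:s, j:j + span_w:s, :]
                dW[i, j] = xs.reshape(-1, c).T @ dyf
                dxp[:, i:i + span_h:s, j:j + span_w:s, :] += \
                    (dyf @ W[i, j].T).reshape(n, oh, ow, c)
        self.grads = {"W": dW, "b": dyf.sum(axis=0)}
        return dxp[:, 1:h + 1, 1:w + 1, :]


class BatchNorm2d:
    """Per-channel batch normalization with learned scale/shift.

    Training mode normalizes with mini-batch statistics and updates running
    estimates (momentum 0.1); eval mode uses the running estimates, which
    makes the eval-mode backward pass a simple per-channel rescaling — the
    case Grad-CAM exercises.
    """

    kind = "batchnorm"

    def __init__(self, channels: int, *, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, training = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        dbeta = dy.sum(axis=(0, 1, 2))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        g = self.params["gamma"] * invstd
        if not training:
            return g * dy
        nhw = dy.shape[0] * dy.shape[1] * dy.shape[2]
        return (g / nhw) * (nhw * dy - dbeta - xhat * dgamma)


class ReLU:
    kind = "relu"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dense:
    """Fully connected layer on (N, F) inputs."""

    kind = "fc"

    def __init__(self, in_features: int, out_features: int,
                 *, rng: np.random.Generator | None = None, dtype=np.float32):
        self.in_features = in_features
        self.out_features = out_features
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params = {
            "W": he_normal(rng, (out_features, in_features), in_features, dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads = {"W": dy.T @ self._x, "b": dy.sum(axis=0)}
        return dy @ self.params["W"]


class Dropout:
    """Inverted dropout; identity in eval mode."""

    kind = "dropout"

    def __init__(self, p: float = 0.5):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            v = self.velocity[k]
            v *= self.momentum
            v -= self.lr * grads[k].astype(p.dtype)
            p += v
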