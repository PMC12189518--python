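"""Minimal numpy neural-network layers (NHWC), sufficient to host frozen
convolutional backbones and a small trainable classification head.

Only the forward pass is implemented for convolutional layers: backbones are
used as fixed feature extractors, so gradients are required only for the dense
head (see :mod:`cdml_eeg.classifier`). Batch-normalization always runs in
inference mode, which is exactly the frozen-backbone contract.
"""

from __future__ import annotations

import math
from typing import Callable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "DepthwiseConv2D", "BatchNorm", "Activation",
    "MaxPool2D", "AvgPool2D", "GlobalAvgPool", "Dense", "Sequential",
    "Residual", "Parallel", "SqueezeExcite", "relu", "swish", "sigmoid",
    "softmax", "count_params",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def swish(x: np.ndarray) -> np.ndarray:
    return x * sigmoid(x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _same_pad(size: int, stride: int, k: int) -> tuple[int, int]:
    """TensorFlow-style SAME padding (excess on the bottom/right)."""
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _pad_nhwc(x: np.ndarray, k: tuple[int, int], stride: int, padding: str) -> np.ndarray:
    if padding == "valid":
        return x
    ph = _same_pad(x.shape[1], stride, k[0])
    pw = _same_pad(x.shape[2], stride, k[1])
    if ph == (0, 0) and pw == (0, 0):
        return x
    return np.pad(x, ((0, 0), ph, pw, (0, 0)))


def _patches(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Return view of sliding patches, shape (N, Ho, Wo, C, kh, kw)."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))
    return v[:, ::stride, ::stride]


class Layer:
    """Base class; parameters are (name, array) pairs discovered by walking."""

    name: str = ""

    def __call__(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def params(self) -> Iterator[tuple[str, np.ndarray]]:
        for key, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield f"{self.name}/{key}" if self.name else key, val
        for child in self.children():
            yield from child.params()

    def children(self) -> Iterator["Layer"]:
        for val in vars(self).values():
            if isinstance(val, Layer):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Layer):
                        yield item


def count_params(layer: Layer) -> int:
    return int(sum(p.size for _, p in layer.params()))


class Conv2D(Layer):
    def __init__(self, cin: int, cout: int, kernel: int | tuple[int, int],
                 stride: int = 1, padding: str = "same", use_bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = ""):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.kh, self.kw, self.stride, self.padding = kh, kw, stride, padding
        self.name = name
        rng = rng or np.random.default_rng(0)
        # He/variance-scaling init on fan_out, the convention of the source nets
        std = math.sqrt(2.0 / (kh * kw * cout))
        self.kernel = rng.normal(0.0, std, (kh, kw, cin, cout)).astype(np.float32)
        if use_bias:
            self.bias = np.zeros(cout, dtype=np.float32)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = _pad_nhwc(x, (self.kh, self.kw), self.stride, self.padding)
        if self.kh == 1 and self.kw == 1:
            out = x[:, ::self.stride, ::self.stride] @ self.kernel[0, 0]
        else:
            p = _patches(x, self.kh, self.kw, self.stride)
            out = np.tensordot(p, self.kernel, axes=([3, 4, 5], [2, 0, 1]))
        if hasattr(self, "bias"):
            out = out + self.bias
        return out


class DepthwiseConv2D(Layer):
    def __init__(self, cin: int, kernel: int, stride: int = 1,
                 padding: str = "same", rng: np.random.Generator | None = None,
                 name: str = ""):
        self.k, self.stride, self.padding = kernel, stride, padding
        self.name = name
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (kernel * kernel))
        self.kernel = rng.normal(0.0, std, (kernel, kernel, cin)).astype(np.float32)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = _pad_nhwc(x, (self.k, self.k), self.stride, self.padding)
        p = _patches(x, self.k, self.k, self.stride)  # N,Ho,Wo,C,kh,kw
        return np.einsum("nhwckl,klc->nhwc", p, self.kernel, optimize=True)


class BatchNorm(Layer):
    """Inference-mode batch normalization.

    ``scale=False`` mirrors architectures that omit gamma (Inception-v3).
    """

    def __init__(self, c: int, scale: bool = True, eps: float = 1e-3, name: str = ""):
        self.eps = eps
        self.name = name
        if scale:
            self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.moving_mean = np.zeros(c, dtype=np.float32)
        self.moving_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        inv = 1.0 / np.sqrt(self.moving_var + self.eps)
        scale = self.gamma * inv if hasattr(self, "gamma") else inv
        return x * scale + (self.beta - self.moving_mean * scale)


class Activation(Layer):
    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]):
        self.fn = fn

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.fn(x)


class MaxPool2D(Layer):
    def __init__(self, pool: int = 2, stride: int | None = None, padding: str = "valid"):
        self.pool, self.stride, self.padding = pool, stride or pool, padding

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = _pad_nhwc(x, (self.pool, self.pool), self.stride, self.padding)
        p = _patches(x, self.pool, self.pool, self.stride)
        return p.max(axis=(4, 5))


class AvgPool2D(Layer):
    def __init__(self, pool: int = 2, stride: int | None = None, padding: str = "valid"):
        self.pool, self.stride, self.padding = pool, stride or pool, padding

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = _pad_nhwc(x, (self.pool, self.pool), self.stride, self.padding)
        p = _patches(x, self.pool, self.pool, self.stride)
        return p.mean(axis=(4, 5))


class GlobalAvgPool(Layer):
    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(1, 2))


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 name: str = ""):
        self.name = name
        rng = rng or np.random.default_rng(0)
        limit = math.sqrt(6.0 / (cin + cout))  # Glorot uniform
        self.kernel = rng.uniform(-limit, limit, (cin, cout)).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x @ self.kernel + self.bias


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer], name: str = ""):
        self.layers = list(layers)
        self.name = name

    def __call__(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x


class Residual(Layer):
    """y = activation(main(x) + shortcut(x)); shortcut=None means identity."""

    def __init__(self, main: Layer, shortcut: Layer | None = None,
                 activation: Callable[[np.ndarray], np.ndarray] | None = None,
                 name: str = ""):
        self.main = main
        self.shortcut = shortcut
        self._act = activation
        self.name = name

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y = self.main(x) + (self.shortcut(x) if self.shortcut is not None else x)
        return self._act(y) if self._act is not None else y


class Parallel(Layer):
    """Concatenate branch outputs along the channel axis (Inception modules)."""

    def __init__(self, branches: Sequence[Layer], name: str = ""):
        self.branches = list(branches)
        self.name = name

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([b(x) for b in self.branches], axis=-1)


class SqueezeExcite(Layer):
    """Squeeze-and-excitation gate: GAP -> 1x1 reduce -> 1x1 expand -> sigmoid."""

    def __init__(self, c: int, c_reduced: int, rng: np.random.Generator | None = None,
                 name: str = ""):
        self.reduce = Conv2D(c, c_reduced, 1, use_bias=True, rng=rng, name=f"{name}/se_reduce")
        self.expand = Conv2D(c_reduced, c, 1, use_bias=True, rng=rng, name=f"{name}/se_expand")
        self.name = name

    def __call__(self, x: np.ndarray) -> np.ndarray:
        s = x.mean(axis=(1, 2), keepdims=True)
        s = swish(self.reduce(s))
        return x * sigmoid(self.expand(s))
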