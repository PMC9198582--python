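"""Minimal neural-network layer library on numpy with hand-written backprop.

Layout is NHWC (channels last, the cache-friendly choice for CPU numpy),
default dtype float32.  Every layer caches what its backward pass needs
during ``forward`` and releases it on the next call, so a layer instance
is single-stream: one forward, then at most one backward.

Convolutions decompose into k*k shifted (strided-view) slices, each
contracted against one kernel tap with a BLAS matmul; the backward pass
runs the same loop with transposed operands plus a strided scatter-add.
This is exact, needs no im2col buffer, and keeps the inner dimension
(channels) contiguous for BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "LeakyReLU",
    "Sigmoid",
    "UpsampleNearest2x",
    "MaxPool2d",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: ``forward(x, train)`` then ``backward(grad_out)``."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype: np.dtype) -> np.ndarray:
    scale = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * scale).astype(dtype)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero or replicate padding.

    Weights are stored HWIO: ``(k, k, in_channels, out_channels)``.

    Parameters
    ----------
    pad_mode : {"zeros", "replicate"}
        Replicate padding repeats edge pixels; its backward pass folds the
        padded-border gradient back onto the edge rows/columns.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, pad_mode: str = "zeros",
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        if pad_mode not in ("zeros", "replicate"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.stride, self.pad, self.pad_mode = stride, padding, pad_mode
        fan_in = in_channels * kernel * kernel
        self.weight = Param(_he_init(rng, (kernel, kernel, in_channels, out_channels),
                                     fan_in, dtype), "conv.weight")
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "conv.bias") if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return x
        p = self.pad
        mode = "constant" if self.pad_mode == "zeros" else "edge"
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode=mode)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        xp = self._pad(x)
        k, s = self.k, self.stride
        ho = (xp.shape[1] - k) // s + 1
        wo = (xp.shape[2] - k) // s + 1
        out = np.zeros((n, ho, wo, self.cout), dtype=x.dtype)
        wv = self.weight.value
        for ki in range(k):
            for kj in range(k):
                sl = xp[:, ki:ki + s * (ho - 1) + 1:s, kj:kj + s * (wo - 1) + 1:s, :]
                out += sl @ wv[ki, kj]
        if self.bias is not None:
            out += self.bias.value
        self._cache = (xp, x.shape, ho, wo)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xp, x_shape, ho, wo = self._cache
        self._cache = None
        n, h, w, c = x_shape
        k, s, p = self.k, self.stride, self.pad
        wv = self.weight.value
        gxp = np.zeros(xp.shape, dtype=grad_out.dtype)
        g2 = grad_out.reshape(n * ho * wo, self.cout)
        for ki in range(k):
            for kj in range(k):
                sl = xp[:, ki:ki + s * (ho - 1) + 1:s, kj:kj + s * (wo - 1) + 1:s, :]
                self.weight.grad[ki, kj] += np.tensordot(
                    sl, grad_out, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, ki:ki + s * (ho - 1) + 1:s, kj:kj + s * (wo - 1) + 1:s, :] += \
                    grad_out @ wv[ki, kj].T
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        if p == 0:
            return gxp
        gx = np.ascontiguousarray(gxp[:, p:p + h, p:p + w, :])
        if self.pad_mode == "replicate":
            # fold padded-border gradient back onto the replicated edges
            gx[:, 0, :, :] += gxp[:, :p, p:p + w, :].sum(axis=1)
            gx[:, -1, :, :] += gxp[:, p + h:, p:p + w, :].sum(axis=1)
            gx[:, :, 0, :] += gxp[:, p:p + h, :p, :].sum(axis=2)
            gx[:, :, -1, :] += gxp[:, p:p + h, p + w:, :].sum(axis=2)
            gx[:, 0, 0, :] += gxp[:, :p, :p, :].sum(axis=(1, 2))
            gx[:, 0, -1, :] += gxp[:, :p, p + w:, :].sum(axis=(1, 2))
            gx[:, -1, 0, :] += gxp[:, p + h:, :p, :].sum(axis=(1, 2))
            gx[:, -1, -1, :] += gxp[:, p + h:, p + w:, :].sum(axis=(1, 2))
        return gx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (out_features, in_features), in_features, dtype),
                            "linear.weight")
        self.bias = Param(np.zeros(out_features, dtype=dtype), "linear.bias")
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += grad_out.T @ x
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32) -> None:
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.astype(self.running_mean.dtype)
            self.running_var = (1 - m) * self.running_var + m * var.astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)) * inv_std
        out = self.gamma.value.astype(x.dtype) * xhat + self.beta.value.astype(x.dtype)
        self._cache = (xhat, inv_std, train, x.shape)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        self._cache = None
        n, h, w, c = shape
        m = n * h * w
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad_out.sum(axis=(0, 1, 2))
        g = grad_out * self.gamma.value.astype(grad_out.dtype)
        if not train:
            return g * inv_std
        # standard batchnorm backward through the batch statistics
        sum_g = g.sum(axis=(0, 1, 2))
        sum_gx = (g * xhat).sum(axis=(0, 1, 2))
        return (inv_std / m) * (m * g - sum_g - xhat * sum_gx)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.2) -> None:
        self.slope = negative_slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, grad_out, self.slope * grad_out)


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.empty_like(x)
        np.negative(x, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        self._out = out
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        out, self._out = self._out, None
        return grad_out * out * (1.0 - out)


class UpsampleNearest2x(Layer):
    """Nearest-neighbour upsampling with scale factor 2."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, h2, w2, c = grad_out.shape
        return grad_out.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (inputs must have even H and W)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = blocks.max(axis=(2, 4))
        self._cache = (blocks, out, x.shape)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        blocks, out, shape = self._cache
        self._cache = None
        mask = blocks == out[:, :, None, :, None, :]
        # split gradient equally across ties (ties are rare on real activations)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (grad_out[:, :, None, :, None, :] / counts)
        return g.reshape(shape)


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        self.shape = shape  # per-sample shape, batch dim implicit

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(grad_out.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class Adam:
    """Adam optimizer (Kingma & Ba) with bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def state_dict(layers: Layer) -> dict[str, np.ndarray]:
    """Flatten all parameters and batchnorm running stats into a dict."""
    state: dict[str, np.ndarray] = {}
    _collect(layers, "", state)
    return state


def load_state_dict(layers: Layer, state: dict[str, np.ndarray]) -> None:
    expected = state_dict(layers)
    missing = set(expected) - set(state)
    if missing:
        raise KeyError(f"checkpoint missing keys: {sorted(missing)}")
    _assign(layers, "", state)


def _iter_children(layer: Layer):
    if isinstance(layer, Sequential):
        for i, child in enumerate(layer.layers):
            yield str(i), child


def _collect(layer: Layer, prefix: str, state: dict[str, np.ndarray]) -> None:
    for name, child in _iter_children(layer):
        _collect(child, f"{prefix}{name}.", state)
    for i, p in enumerate(_own_params(layer)):
        state[f"{prefix}p{i}"] = p.value
    if isinstance(layer, BatchNorm2d):
        state[f"{prefix}running_mean"] = layer.running_mean
        state[f"{prefix}running_var"] = layer.running_var


def _assign(layer: Layer, prefix: str, state: dict[str, np.ndarray]) -> None:
    for name, child in _iter_children(layer):
        _assign(child, f"{prefix}{name}.", state)
    for i, p in enumerate(_own_params(layer)):
        p.value = np.asarray(state[f"{prefix}p{i}"], dtype=p.value.dtype).reshape(p.value.shape)
        p.grad = np.zeros_like(p.value)
    if isinstance(layer, BatchNorm2d):
        layer.running_mean = np.asarray(state[f"{prefix}running_mean"],
                                        dtype=layer.running_mean.dtype)
        layer.running_var = np.asarray(state[f"{prefix}running_var"],
                                       dtype=layer.running_var.dtype)


def _own_params(layer: Layer) -> list[Param]:
    if isinstance(layer, Sequential):
        return []
    return layer.params()
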