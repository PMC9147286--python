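"""Layer primitives with explicit forward/backward passes.

Conventions
-----------
* Activations are float32, layout ``(N, C, H, W)`` for spatial layers and
  ``(N, D)`` for dense layers.
* ``forward(x, train=...)`` caches whatever the matching ``backward(dy)``
  needs; layers are therefore stateful between the two calls and a layer
  instance must not be shared across concurrent passes.
* Weight initialization draws from a ``numpy.random.Generator`` supplied at
  construction, so a model built twice from the same seed has bit-identical
  parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "Linear",
    "Sequential",
    "sigmoid",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: a differentiable map with optional parameters."""

    def params(self) -> list[Param]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col matrix multiply."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ) -> None:
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.padding = stride, padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_he_init(rng, (out_channels, fan_in), fan_in), "conv.weight")
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), "conv.bias")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = self._im2col(xp)
        out = cols @ self.weight.value.T + self.bias.value
        n = x.shape[0]
        y = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        self._cache = (x.shape, xp.shape, cols, ho, wo)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols, ho, wo = self._cache
        n = x_shape[0]
        k, s, p = self.k, self.stride, self.padding
        dout = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.weight.grad += dout.T @ cols
        self.bias.grad += dout.sum(axis=0)
        dcols = dout @ self.weight.value  # (N*Ho*Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, self.cin, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        # scatter-add one kernel offset at a time; each slice is a strided view
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c = x.shape[1]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        y = self.gamma.value.reshape(1, c, 1, 1) * xhat + self.beta.value.reshape(1, c, 1, 1)
        self._cache = (xhat, inv, train, x.shape)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        c = shape[1]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value.reshape(1, c, 1, 1)
        if not train:
            return (dy * g * inv.reshape(1, c, 1, 1)).astype(np.float32)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv.reshape(1, c, 1, 1)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride); H, W must divide."""

    def __init__(self, size: int = 2) -> None:
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {s}")
        xr = x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // s, w // s, s * s)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        s = self.size
        dxr = np.zeros((n, c, h // s, w // s, s * s), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class GlobalAvgPool2d(Layer):
    """(N, C, H, W) -> (N, C) mean over the spatial extent."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._in_shape).astype(
            np.float32
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        self.weight = Param(_he_init(rng, (out_features, in_features), in_features), "fc.weight")
        self.bias = Param(np.zeros(out_features, dtype=np.float32), "fc.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.value).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def state(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            own = layer.state()
            for k in own:
                own[k][...] = state[f"{i}.{k}"]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    return np.where(
        np.asarray(x) >= 0,
        1.0 / (1.0 + np.exp(-np.clip(x, -60, 60))),
        np.exp(np.clip(x, -60, 60)) / (1.0 + np.exp(np.clip(x, -60, 60))),
    )
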