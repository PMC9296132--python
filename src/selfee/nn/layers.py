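"""Layers with explicit forward caches and hand-written backward passes."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Linear",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Sequential",
    "Residual",
    "NormalizedLinear",
    "L2Normalize",
    "l2_normalize",
]


def l2_normalize(x: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    """Rows (or the given axis) scaled to unit Euclidean norm."""
    norm = np.sqrt(np.sum(np.square(x), axis=axis, keepdims=True))
    return x / np.maximum(norm, eps)


class Param:
    """A trainable array with an accumulated gradient.

    ``kind`` is one of ``weight`` / ``bias`` / ``bn`` and controls whether
    weight decay applies (only to ``weight``).
    """

    __slots__ = ("name", "value", "grad", "kind")

    def __init__(self, name: str, value: np.ndarray, kind: str = "weight"):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.kind = kind

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        return {}

    def forward(self, x: np.ndarray, train: bool):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False):
        return self.forward(x, train)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32, name: str = "linear"):
        scale = np.sqrt(2.0 / in_dim)
        w = rng.normal(0.0, scale, size=(out_dim, in_dim)).astype(dtype)
        self.weight = Param(f"{name}.weight", w, "weight")
        self.bias = Param(f"{name}.bias", np.zeros(out_dim, dtype=dtype), "bias") if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train):
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y, x

    def backward(self, dy, cache):
        x = cache
        self.weight.grad += dy.T @ x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = x[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += dcols[:, :, ki, kj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    """2-D convolution (NCHW) via im2col; no bias by default (batch-norm follows)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, pad: int | None = None,
                 bias: bool = False, *, rng: np.random.Generator, dtype=np.float32,
                 name: str = "conv"):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (in_ch * k * k))
        w = rng.normal(0.0, scale, size=(out_ch, in_ch, k, k)).astype(dtype)
        self.weight = Param(f"{name}.weight", w, "weight")
        self.bias = Param(f"{name}.bias", np.zeros(out_ch, dtype=dtype), "bias") if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wm = self.weight.value.reshape(self.weight.value.shape[0], -1)
        y = (wm @ cols).reshape(x.shape[0], -1, ho, wo)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        return y, (x.shape, cols, ho, wo)

    def backward(self, dy, cache):
        x_shape, cols, ho, wo = cache
        n, co = dy.shape[:2]
        dym = dy.reshape(n, co, ho * wo)
        wm = self.weight.value.reshape(co, -1)
        self.weight.grad += np.einsum("nol,nfl->of", dym, cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dym.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", wm, dym)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class BatchNorm(Layer):
    """Batch normalization for (N, C) or (N, C, H, W) inputs.

    Training uses population statistics of the current batch; running
    statistics (for eval mode) track the batch statistics with momentum 0.1.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5, *,
                 dtype=np.float32, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(num_features, dtype=dtype), "bn")
        self.beta = Param(f"{name}.beta", np.zeros(num_features, dtype=dtype), "bn")
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    @staticmethod
    def _to2d(x):
        if x.ndim == 2:
            return x, None
        n, c, h, w = x.shape
        return x.transpose(0, 2, 3, 1).reshape(-1, c), (n, h, w, c)

    @staticmethod
    def _from2d(y, shape):
        if shape is None:
            return y
        n, h, w, c = shape
        return y.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def forward(self, x, train):
        x2, shape = self._to2d(x)
        if train:
            mu = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x2 - mu) * invstd
        y = self.gamma.value * xhat + self.beta.value
        return self._from2d(y, shape), (xhat, invstd, shape, train)

    def backward(self, dy, cache):
        xhat, invstd, shape, train = cache
        dy2, _ = self._to2d(dy)
        self.gamma.grad += (dy2 * xhat).sum(axis=0)
        self.beta.grad += dy2.sum(axis=0)
        g = self.gamma.value * invstd
        if not train:
            return self._from2d(dy2 * g, shape)
        m = dy2.shape[0]
        dx2 = g * (dy2 - dy2.mean(axis=0) - xhat * (dy2 * xhat).sum(axis=0) / m)
        return self._from2d(dx2, shape)


class ReLU(Layer):
    def forward(self, x, train):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int | None = None, pad: int = 0):
        self.k = k
        self.stride = stride or k
        self.pad = pad

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        if self.pad:
            xr = np.pad(xr, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                        constant_values=-np.inf)
        cols, ho, wo = _im2col(xr, self.k, self.stride, 0)
        idx = cols.argmax(axis=1)
        y = np.take_along_axis(cols, idx[:, None, :], axis=1)[:, 0]
        return y.reshape(n, c, ho, wo), (x.shape, idx, ho, wo)

    def backward(self, dy, cache):
        x_shape, idx, ho, wo = cache
        n, c, h, w = x_shape
        dcols = np.zeros((n * c, self.k * self.k, ho * wo), dtype=dy.dtype)
        np.put_along_axis(dcols, idx[:, None, :], dy.reshape(n * c, 1, ho * wo), axis=1)
        dxp = _col2im(dcols, (n * c, 1, h + 2 * self.pad, w + 2 * self.pad),
                      self.k, self.stride, 0, ho, wo)
        if self.pad:
            dxp = dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.buffers().items():
                out[f"{i}.{key}"] = val
        return out

    def forward(self, x, train):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy


class Residual(Layer):
    """``relu(main(x) + shortcut(x))``; identity shortcut when none given."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main = main
        self.shortcut = shortcut

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def buffers(self):
        out = {f"main.{k}": v for k, v in self.main.buffers().items()}
        if self.shortcut is not None:
            out.update({f"short.{k}": v for k, v in self.shortcut.buffers().items()})
        return out

    def forward(self, x, train):
        ym, cm = self.main.forward(x, train)
        if self.shortcut is not None:
            ys, cs = self.shortcut.forward(x, train)
        else:
            ys, cs = x, None
        s = ym + ys
        mask = s > 0
        return s * mask, (cm, cs, mask)

    def backward(self, dy, cache):
        cm, cs, mask = cache
        ds = dy * mask
        dx = self.main.backward(ds, cm)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(ds, cs)
        else:
            dx = dx + ds
        return dx


class NormalizedLinear(Layer):
    """Weight-normalized linear map followed by L2 normalization of outputs.

    Weight rows are scaled to unit norm at every forward pass and each
    output vector is scaled to unit norm, so outputs live on the sphere.
    """

    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator,
                 dtype=np.float32, name: str = "normlinear"):
        w = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(out_dim, in_dim)).astype(dtype)
        self.weight = Param(f"{name}.weight", w, "weight")

    def params(self):
        return [self.weight]

    def forward(self, x, train):
        w = self.weight.value
        wnorm = np.sqrt(np.sum(w * w, axis=1, keepdims=True))
        what = w / np.maximum(wnorm, 1e-12)
        u = x @ what.T
        unorm = np.sqrt(np.sum(u * u, axis=1, keepdims=True))
        y = u / np.maximum(unorm, 1e-12)
        return y, (x, what, wnorm, unorm, y)

    def backward(self, dy, cache):
        x, what, wnorm, unorm, y = cache
        # through output normalization: du = (dy - (dy.y) y) / |u|
        du = (dy - np.sum(dy * y, axis=1, keepdims=True) * y) / np.maximum(unorm, 1e-12)
        dx = du @ what
        dwhat = du.T @ x
        # through weight normalization, row-wise
        dw = (dwhat - np.sum(dwhat * what, axis=1, keepdims=True) * what) / np.maximum(wnorm, 1e-12)
        self.weight.grad += dw
        return dx


class L2Normalize(Layer):
    def forward(self, x, train):
        norm = np.sqrt(np.sum(x * x, axis=1, keepdims=True))
        y = x / np.maximum(norm, 1e-12)
        return y, (y, norm)

    def backward(self, dy, cache):
        y, norm = cache
        return (dy - np.sum(dy * y, axis=1, keepdims=True) * y) / np.maximum(norm, 1e-12)
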