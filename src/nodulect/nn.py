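"""Minimal 3D neural-network core (numpy, explicit backprop).

Implements exactly the pieces the fusion classifier needs: 3D
convolution (im2col + GEMM), 3D batch normalization, max/global-average
pooling, linear layers, ReLU, inverted dropout, the bottleneck residual
block U(x) = R(x) + M(x), the Adam optimizer and binary cross-entropy
on logits.  Tensors are (N, C, D, H, W); float32 by default, with
float64 available for numeric gradient checks.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Layer", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d", "GlobalAvgPool",
    "Linear", "Dropout", "Sequential", "Bottleneck", "Adam",
    "bce_with_logits", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient wrt the logits."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


class Layer:
    """Base: forward caches what backward needs; params/grads are dicts."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def named_params(self, prefix: str = "") -> Iterator[Tuple[str, "Layer", str]]:
        for name in self.params:
            yield f"{prefix}{name}", self, name


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Do, Ho, Wo, k, k, k) view over a padded (N, C, D, H, W) array."""
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return w[:, :, ::stride, ::stride, ::stride]


class Conv3d(Layer):
    """3D convolution via im2col; He-initialised, optional bias."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k ** 3
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.dtype = dtype
        self.params["w"] = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xshape, self._pshape = x.shape, xp.shape
        win = _windows(xp, k, s)                       # N,C,Do,Ho,Wo,k,k,k
        n, c, do, ho, wo = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * k ** 3)
        self._cols = np.ascontiguousarray(cols, dtype=self.dtype)
        self._out_sp = (do, ho, wo)
        out = self._cols @ self.params["w"].T
        if "b" in self.params:
            out += self.params["b"]
        return out.reshape(n, do, ho, wo, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n = gout.shape[0]
        do, ho, wo = self._out_sp
        g2 = gout.transpose(0, 2, 3, 4, 1).reshape(-1, self.cout).astype(self.dtype)
        self.grads["w"] = g2.T @ self._cols
        if "b" in self.params:
            self.grads["b"] = g2.sum(axis=0)
        gcols = (g2 @ self.params["w"]).reshape(n, do, ho, wo, self.cin, k, k, k)
        gxp = np.zeros(self._pshape, dtype=self.dtype)
        gc = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)   # N,C,Do,Ho,Wo,k,k,k
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    gxp[:, :, a:a + s * do:s, b:b + s * ho:s, c:c + s * wo:s] += gc[..., a, b, c]
        self._cols = None
        if p:
            return gxp[:, :, p:-p, p:-p, p:-p]
        return gxp


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean.astype(np.float64) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float64) - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self.params["gamma"][None, :, None, None, None] * xhat + self.params["beta"][None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, invstd = self._xhat, self._invstd
        self.grads["gamma"] = (gout * xhat).sum(axis=axes)
        self.grads["beta"] = gout.sum(axis=axes)
        gxhat = gout * self.params["gamma"][None, :, None, None, None]
        if not self._train:
            return gxhat * invstd[None, :, None, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3] * gout.shape[4]
        s1 = gxhat.sum(axis=axes)[None, :, None, None, None]
        s2 = (gxhat * xhat).sum(axis=axes)[None, :, None, None, None]
        return (invstd[None, :, None, None, None] / m) * (m * gxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool3d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), constant_values=-np.inf)
        self._pshape, self._xdtype = xp.shape, x.dtype
        win = _windows(xp, k, s)
        n, c, do, ho, wo = win.shape[:5]
        flat = win.reshape(n, c, do, ho, wo, k ** 3)
        self._arg = flat.argmax(axis=-1)
        self._out_sp = (do, ho, wo)
        return flat.max(axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        do, ho, wo = self._out_sp
        gxp = np.zeros(self._pshape, dtype=self._xdtype)
        for idx in range(k ** 3):
            sel = self._arg == idx
            if not sel.any():
                continue
            a, rem = divmod(idx, k * k)
            b, c = divmod(rem, k)
            gxp[:, :, a:a + s * do:s, b:b + s * ho:s, c:c + s * wo:s] += gout * sel
        if p:
            return gxp[:, :, p:-p, p:-p, p:-p]
        return gxp


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._sp = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        d, h, w = self._sp
        g = gout[:, :, None, None, None] / (d * h * w)
        return np.broadcast_to(g, gout.shape + self._sp).astype(gout.dtype)


class Linear(Layer):
    def __init__(self, fin: int, fout: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = (rng.standard_normal((fout, fin)) * np.sqrt(2.0 / fin)).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(fout, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.params["w"].T
        if "b" in self.params:
            out += self.params["b"]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["w"] = gout.T @ self._x
        if "b" in self.params:
            self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["w"]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def named_params(self, prefix: str = "") -> Iterator[Tuple[str, Layer, str]]:
        for i, layer in enumerate(self.layers):
            yield from layer.named_params(f"{prefix}{i}.")


class Bottleneck(Layer):
    """Residual bottleneck: 1x1x1 -> 3x3x3(stride) -> 1x1x1, plus skip.

    U(x) = R(x) + M(x); M is the identity when input and output shapes
    agree, otherwise a strided 1x1x1 projection with batch norm.
    """

    def __init__(self, cin: int, cmid: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.main = Sequential(
            Conv3d(cin, cmid, 1, rng=rng, dtype=dtype), BatchNorm3d(cmid, dtype=dtype), ReLU(),
            Conv3d(cmid, cmid, 3, stride=stride, pad=1, rng=rng, dtype=dtype), BatchNorm3d(cmid, dtype=dtype), ReLU(),
            Conv3d(cmid, cout, 1, rng=rng, dtype=dtype), BatchNorm3d(cout, dtype=dtype),
        )
        if stride != 1 or cin != cout:
            self.skip: Layer | None = Sequential(
                Conv3d(cin, cout, 1, stride=stride, rng=rng, dtype=dtype), BatchNorm3d(cout, dtype=dtype)
            )
        else:
            self.skip = None
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        r = self.main.forward(x, train=train)
        m = x if self.skip is None else self.skip.forward(x, train=train)
        return self.relu.forward(r + m, train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu.backward(gout)
        gx = self.main.backward(g)
        gx = gx + (g if self.skip is None else self.skip.backward(g))
        return gx

    def named_params(self, prefix: str = "") -> Iterator[Tuple[str, Layer, str]]:
        yield from self.main.named_params(f"{prefix}main.")
        if self.skip is not None:
            yield from self.skip.named_params(f"{prefix}skip.")


class Adam:
    """Adam over every parameter reachable from the given root layers."""

    def __init__(self, roots: Sequence[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.entries: List[Tuple[str, Layer, str]] = []
        for i, root in enumerate(roots):
            self.entries.extend(root.named_params(f"root{i}."))
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {name: np.zeros_like(layer.params[key], dtype=np.float64)
                  for name, layer, key in self.entries}
        self.v = {name: np.zeros_like(layer.params[key], dtype=np.float64)
                  for name, layer, key in self.entries}
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, layer, key in self.entries:
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self.m[name]
            v = self.v[name]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g.astype(np.float64) ** 2 - v)
            update = lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            layer.params[key] -= update.astype(layer.params[key].dtype)

    def n_params(self) -> int:
        return sum(layer.params[key].size for _, layer, key in self.entries)
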