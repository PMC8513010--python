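"""Minimal NumPy neural-network engine.

Implements exactly the pieces the stroke classifiers need: stride-1
"same" 2-D convolution (shift-accumulate GEMM formulation), max pooling,
batch normalization, global average pooling, a fully connected layer,
softmax cross-entropy, and Adam.  Layers expose ``forward(x, train)``
and ``backward(grad)``; parameters are ``Param`` objects collected by
the optimizer.

All tensors are ``float32`` in channels-last ``(B, H, W, C)`` layout,
which lets every convolution offset reduce to a contiguous
``(B*H*W, C_in) @ (C_in, C_out)`` matrix product.

Determinism: every weight initialization draws from an explicitly passed
``numpy.random.Generator``; no global random state is touched.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Stride-1 'same' convolution, He-initialized.

    Computed as a sum over the ``kh*kw`` kernel offsets of a
    ``(B*H*W, C_in) @ (C_in, C_out)`` GEMM, which for the small channel
    counts used here beats materializing an im2col buffer.
    """

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kh * kw
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (kh, kw, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self.kh, self.kw = kh, kw
        self.in_ch, self.out_ch = in_ch, out_ch
        self._x_pad: np.ndarray | None = None

    def _pads(self) -> tuple[int, int, int, int]:
        ph, pw = self.kh - 1, self.kw - 1
        return ph // 2, ph - ph // 2, pw // 2, pw - pw // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        ph0, ph1, pw0, pw1 = self._pads()
        xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
        self._x_pad = xp if train else None
        self._shape = (b, h, w, c)
        y = np.zeros((b, h, w, self.out_ch), dtype=DTYPE)
        y += self.b.value
        for i in range(self.kh):
            for j in range(self.kw):
                y += xp[:, i : i + h, j : j + w, :] @ self.w.value[i, j]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x_pad is not None, "backward before forward(train=True)"
        b, h, w, c = self._shape
        ph0, ph1, pw0, pw1 = self._pads()
        dxp = np.zeros_like(self._x_pad)
        self.b.grad += grad.sum(axis=(0, 1, 2))
        gflat = grad.reshape(-1, self.out_ch)
        for i in range(self.kh):
            for j in range(self.kw):
                patch = self._x_pad[:, i : i + h, j : j + w, :]
                self.w.grad[i, j] += patch.reshape(-1, c).T @ gflat
                dxp[:, i : i + h, j : j + w, :] += grad @ self.w.value[i, j].T
        return dxp[:, ph0 : ph0 + h, pw0 : pw0 + w, :]

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """Max pooling; ``same=True`` keeps the spatial extent (stride 1)."""

    def __init__(self, k: int, stride: int, same: bool = False):
        self.k, self.stride, self.same = k, stride, same

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        if self.same:
            if self.stride != 1:
                raise ValueError("'same' pooling requires stride 1")
            p = self.k - 1
            xp = np.pad(x, ((0, 0), (p // 2, p - p // 2),
                            (p // 2, p - p // 2), (0, 0)),
                        constant_values=-np.inf)
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (self.k, self.k), axis=(1, 2))[:, ::self.stride, ::self.stride]
        bb, ho, wo, cc, _, _ = win.shape
        flat = win.reshape(bb, ho, wo, cc, self.k * self.k)
        self._arg = np.argmax(flat, axis=-1)
        self._in_shape, self._pad_shape = x.shape, xp.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, ho, wo, c = grad.shape
        dxp = np.zeros(self._pad_shape, dtype=grad.dtype)
        oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        ii = oi[None, :, :, None] * self.stride + self._arg // self.k
        jj = oj[None, :, :, None] * self.stride + self._arg % self.k
        bi = np.arange(b)[:, None, None, None]
        ci = np.arange(c)[None, None, None, :]
        np.add.at(dxp, (bi, ii, jj, ci), grad)
        if self.same:
            p = self.k - 1
            h, w = self._in_shape[1], self._in_shape[2]
            return dxp[:, p // 2 : p // 2 + h, p // 2 : p // 2 + w, :]
        return dxp[:, : self._in_shape[1], : self._in_shape[2], :]


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / std
        self._std = std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        gm = g.mean(axis=(0, 1, 2), keepdims=True)
        gxm = (g * self._xhat).mean(axis=(0, 1, 2), keepdims=True)
        return (g - gm - self._xhat * gxm) / self._std

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Identity(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Branches(Layer):
    """Parallel branches concatenated along the channel axis."""

    def __init__(self, *branches: Layer):
        self.branches = list(branches)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        outs = [br.forward(x, train) for br in self.branches]
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        parts = np.split(grad, self._splits, axis=-1)
        total = None
        for br, g in zip(self.branches, parts):
            dx = br.backward(np.ascontiguousarray(g))
            total = dx if total is None else total + dx
        return total

    def params(self) -> list[Param]:
        return [p for br in self.branches for p in br.params()]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax: exp(x_i) / sum_i exp(x_i), numerically shifted."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def count_params(layer: Layer) -> int:
    return sum(p.value.size for p in layer.params())
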