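"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the package's small trainable
networks: broadcast arithmetic, matmul, 2-D convolution (via im2col),
nearest-neighbour upsampling, channel concatenation, pointwise
nonlinearities, reductions, softmax, and fused stable losses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "upsample2x", "concat", "softmax",
           "bce_with_logits", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._prev = (self,)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        out._prev = (self,)
        inv = np.argsort(axes)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))
        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        out._prev = (self,)

        def _bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                for a in sorted(a % self.data.ndim for a in ax):
                    g = np.expand_dims(g, a)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        out._prev = (self,)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))
        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, self.requires_grad)
        out._prev = (self,)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))
        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad)
        out._prev = (self,)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - t * t))
        out._backward = _bw
        return out


# -- convolution ---------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp = (x.shape[2] - kh) // stride + 1
    wp = (x.shape[3] - kw) // stride + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, hp, wp, c, kh, kw),
        (s[0], s[2] * stride, s[3] * stride, s[1], s[2], s[3]))
    return np.ascontiguousarray(cols).reshape(n * hp * wp, c * kh * kw), hp, wp, x.shape


def _col2im(dcols: np.ndarray, padded_shape, kh, kw, stride, hp, wp, pad):
    n, c, h, w = padded_shape
    dx = np.zeros(padded_shape)
    dcols = dcols.reshape(n, hp, wp, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + hp * stride:stride, j:j + wp * stride:stride] += \
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N,C,H,W); w: (O,C,kh,kw); b: (O,). Returns (N,O,H',W')."""
    o, c, kh, kw = w.data.shape
    cols, hp, wp, padded_shape = _im2col(x.data, kh, kw, stride, pad)
    wm = w.data.reshape(o, -1)
    y = cols @ wm.T + b.data
    n = x.data.shape[0]
    out = Tensor(y.reshape(n, hp, wp, o).transpose(0, 3, 1, 2),
                 x.requires_grad or w.requires_grad or b.requires_grad)
    out._prev = (x, w, b)

    def _bw():
        dy = out.grad.transpose(0, 2, 3, 1).reshape(-1, o)
        if b.requires_grad:
            b._accum(dy.sum(axis=0))
        if w.requires_grad:
            w._accum((dy.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            x._accum(_col2im(dy @ wm, padded_shape, kh, kw, stride, hp, wp, pad))
    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (N,C,H,W)."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), x.requires_grad)
    out._prev = (x,)

    def _bw():
        if x.requires_grad:
            n, c, h, w = x.data.shape
            x._accum(out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    out._backward = _bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    out._prev = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw():
        offs = np.cumsum([0] + sizes)
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(a, b)
                t._accum(out.grad[tuple(idx)])
    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, x.requires_grad)
    out._prev = (x,)

    def _bw():
        if x.requires_grad:
            g = out.grad
            x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits; numerically stable."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), logits.requires_grad)
    out._prev = (logits,)

    def _bw():
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accum(out.grad * (p - y) / z.size)
    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean multiclass cross-entropy on logits (N,K) vs one-hot (N,K)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    y = np.asarray(onehot, dtype=np.float64)
    out = Tensor(-(y * logp).sum(axis=1).mean(), logits.requires_grad)
    out._prev = (logits,)

    def _bw():
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accum(out.grad * (p - y) / z.shape[0])
    out._backward = _bw
    return out
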