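"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the denoiser and predictor need: broadcasted
arithmetic, matmul, 1-D convolution (via im2col), nearest-neighbour upsampling,
reductions, reshaping/concatenation, sigmoid/SiLU, and a numerically stable
binary cross-entropy on logits. Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward` in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "upsample_nearest", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        g = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = backward
        return out

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward
        return out

    # -- nonlinearities --------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        val = self.data * s
        out = Tensor(val, self.requires_grad, (self,))
        # d/dx x*sigma(x) = sigma(x) * (1 + x*(1-sigma(x)))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * s * (1.0 + self.data * (1.0 - s))
        )
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(
        np.concatenate(datas, axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, L) -> (N, C*k, L_out) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    n, c, l = x.shape
    l_out = (l - k) // stride + 1
    cols = np.empty((n, c, k, l_out), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j, :] = x[:, :, j : j + stride * l_out : stride]
    return cols.reshape(n, c * k, l_out)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, l = x_shape
    l_pad = l + 2 * pad
    l_out = cols.shape[-1]
    cols = cols.reshape(n, c, k, l_out)
    x = np.zeros((n, c, l_pad), dtype=cols.dtype)
    for j in range(k):
        # scatter-add each tap back to its source positions
        np.add.at(x, (slice(None), slice(None), slice(j, j + stride * l_out, stride)), cols[:, :, j, :])
    return x[:, :, pad : pad + l] if pad else x


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """1-D convolution. x: (N, C_in, L); w: (C_out, C_in, K); b: (C_out,)."""
    n = x.data.shape[0]
    c_out, c_in, k = w.data.shape
    cols = _im2col(x.data, k, stride, pad)  # (N, C_in*k, L_out)
    w_mat = w.data.reshape(c_out, c_in * k)
    val = np.einsum("ok,nkl->nol", w_mat, cols, optimize=True)
    if b is not None:
        val = val + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, any(t.requires_grad for t in parents), parents)

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", g, cols, optimize=True)
            w._accum(gw.reshape(c_out, c_in, k))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("ok,nol->nkl", w_mat, g, optimize=True)
            x._accum(_col2im(gcols, x.data.shape, k, stride, pad))

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling along the last (position) axis."""
    out = Tensor(np.repeat(x.data, factor, axis=-1), x.requires_grad, (x,))

    def backward(g):
        if x.requires_grad:
            n, c, l = x.data.shape
            x._accum(g.reshape(n, c, l, factor).sum(axis=-1))

    out._backward = backward
    return out


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits, numerically stable."""
    y = np.asarray(y, dtype=np.float64)
    zd = z.data
    # log(1+e^z) - y*z, computed stably
    val = np.maximum(zd, 0.0) - y * zd + np.log1p(np.exp(-np.abs(zd)))
    out = Tensor(val.mean(), z.requires_grad, (z,))

    def backward(g):
        if z.requires_grad:
            p = 1.0 / (1.0 + np.exp(-zd))
            z._accum(g * (p - y) / zd.size)

    out._backward = backward
    return out
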