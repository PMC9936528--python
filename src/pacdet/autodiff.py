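"""Lightweight reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the rest of the package needs:
elementwise arithmetic, matmul, softmax, strided convolution, max pooling,
bilinear 2x upsampling, indexing and reductions.  Graphs are built eagerly;
calling :meth:`Tensor.backward` on a scalar accumulates gradients into every
reachable ``requires_grad`` tensor's ``.grad``.

Model code runs in ``float32``; every op preserves the input dtype, so tests
can run the identical code path in ``float64`` when comparing against
central-difference gradients.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data, dtype=dtype)
        if dtype is None and not isinstance(data, np.ndarray) and arr.dtype == np.float64:
            arr = arr.astype(np.float32)  # python scalars/lists default to float32
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[], None] | None) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = ()
        out._backward = None
        out.requires_grad = False
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- misc ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, "
                f"requires_grad={self.requires_grad})")

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _acc(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._acc(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ---------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        a, b = self, self._coerce(other)
        out = Tensor._make(a.data + b.data, (a, b), None)

        def bwd():
            a._acc(_unbroadcast(out.grad, a.shape))
            b._acc(_unbroadcast(out.grad, b.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor._make(-a.data, (a,), None)
        out._backward = lambda: a._acc(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._coerce(other)
        out = Tensor._make(a.data * b.data, (a, b), None)

        def bwd():
            a._acc(_unbroadcast(out.grad * b.data, a.shape))
            b._acc(_unbroadcast(out.grad * a.data, b.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._coerce(other)
        out = Tensor._make(a.data / b.data, (a, b), None)

        def bwd():
            a._acc(_unbroadcast(out.grad / b.data, a.shape))
            b._acc(_unbroadcast(-out.grad * a.data / (b.data * b.data), b.shape))
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        out = Tensor._make(a.data ** p, (a,), None)
        out._backward = lambda: a._acc(out.grad * p * a.data ** (p - 1))
        return out

    def __matmul__(self, other):
        a, b = self, self._coerce(other)
        out = Tensor._make(a.data @ b.data, (a, b), None)

        def bwd():
            a._acc(_unbroadcast(out.grad @ np.swapaxes(b.data, -1, -2), a.shape))
            b._acc(_unbroadcast(np.swapaxes(a.data, -1, -2) @ out.grad, b.shape))
        out._backward = bwd
        return out

    # -- elementwise functions ----------------------------------------
    def exp(self):
        a = self
        data = np.exp(a.data)
        out = Tensor._make(data, (a,), None)
        out._backward = lambda: a._acc(out.grad * data)
        return out

    def log(self):
        a = self
        out = Tensor._make(np.log(a.data), (a,), None)
        out._backward = lambda: a._acc(out.grad / a.data)
        return out

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)
        out = Tensor._make(data, (a,), None)
        out._backward = lambda: a._acc(out.grad / (2.0 * data))
        return out

    def arctan(self):
        a = self
        out = Tensor._make(np.arctan(a.data), (a,), None)
        out._backward = lambda: a._acc(out.grad / (1.0 + a.data * a.data))
        return out

    def relu(self):
        a = self
        mask = a.data > 0
        out = Tensor._make(a.data * mask, (a,), None)
        out._backward = lambda: a._acc(out.grad * mask)
        return out

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor._make(data, (a,), None)
        out._backward = lambda: a._acc(out.grad * data * (1.0 - data))
        return out

    def maximum(self, other):
        a, b = self, self._coerce(other)
        amask = a.data >= b.data  # ties route the subgradient to the first arg
        out = Tensor._make(np.where(amask, a.data, b.data), (a, b), None)

        def bwd():
            a._acc(_unbroadcast(out.grad * amask, a.shape))
            b._acc(_unbroadcast(out.grad * ~amask, b.shape))
        out._backward = bwd
        return out

    def minimum(self, other):
        a, b = self, self._coerce(other)
        amask = a.data <= b.data
        out = Tensor._make(np.where(amask, a.data, b.data), (a, b), None)

        def bwd():
            a._acc(_unbroadcast(out.grad * amask, a.shape))
            b._acc(_unbroadcast(out.grad * ~amask, b.shape))
        out._backward = bwd
        return out

    def clamp_min(self, lo: float):
        return self.maximum(Tensor(np.asarray(lo, dtype=self.data.dtype)))

    # -- reductions & shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), None)

        def bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._acc(np.broadcast_to(g, a.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out = Tensor._make(a.data.reshape(shape), (a,), None)
        out._backward = lambda: a._acc(out.grad.reshape(a.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        out = Tensor._make(a.data.transpose(axes), (a,), None)
        out._backward = lambda: a._acc(out.grad.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]
        out = Tensor._make(data.copy() if isinstance(data, np.ndarray) else np.asarray(data),
                           (a,), None)

        def bwd():
            g = np.zeros_like(a.data)
            np.add.at(g, idx, out.grad)
            a._acc(g)
        out._backward = bwd
        return out

    # -- neural-net primitives ------------------------------------------
    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(s, (a,), None)

        def bwd():
            dot = (out.grad * s).sum(axis=axis, keepdims=True)
            a._acc((out.grad - dot) * s)
        out._backward = bwd
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """NCHW convolution; weight (Cout, Cin, kh, kw), bias (Cout,)."""
        a, w = self, weight
        x = a.data
        N, C, H, W = x.shape
        Cout, Cin, kh, kw = w.shape
        if Cin != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Cin}")
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Hp, Wp = x.shape[2], x.shape[3]
        OH = (Hp - kh) // stride + 1
        OW = (Wp - kw) // stride + 1
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N, OH * OW, C * kh * kw)
        wmat = w.data.reshape(Cout, C * kh * kw)
        res = cols @ wmat.T  # (N, OH*OW, Cout)
        res = res.transpose(0, 2, 1).reshape(N, Cout, OH, OW)
        if bias is not None:
            res = res + bias.data.reshape(1, Cout, 1, 1)
        parents = (a, w) if bias is None else (a, w, bias)
        out = Tensor._make(res, parents, None)

        def bwd():
            g = out.grad
            gmat = g.reshape(N, Cout, OH * OW).transpose(0, 2, 1)  # (N, OH*OW, Cout)
            gw = np.einsum("npo,npk->ok", gmat, cols).reshape(w.shape)
            w._acc(gw.astype(w.data.dtype, copy=False))
            if bias is not None:
                bias._acc(g.sum(axis=(0, 2, 3)).astype(bias.data.dtype, copy=False))
            if a.requires_grad:
                gcols = (gmat @ wmat).reshape(N, OH, OW, C, kh, kw)
                gx = np.zeros((N, C, Hp, Wp), dtype=x.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += \
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gx = gx[:, :, padding:Hp - padding, padding:Wp - padding]
                a._acc(gx)
        out._backward = bwd
        return out

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0):
        """Max pooling over NCHW; padding uses the dtype minimum so it never wins."""
        a = self
        x = a.data
        N, C, H, W = x.shape
        if padding:
            fill = np.finfo(x.dtype).min
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                       constant_values=fill)
        Hp, Wp = x.shape[2], x.shape[3]
        OH = (Hp - kernel) // stride + 1
        OW = (Wp - kernel) // stride + 1
        win = sliding_window_view(x, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
        flat = win.reshape(N, C, OH, OW, kernel * kernel)
        arg = flat.argmax(axis=-1)
        data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        out = Tensor._make(data.copy(), (a,), None)

        def bwd():
            gx = np.zeros((N, C, Hp, Wp), dtype=x.dtype)
            ki, kj = np.unravel_index(arg, (kernel, kernel))
            n_i, c_i, oh_i, ow_i = np.indices(arg.shape, sparse=False)
            np.add.at(gx, (n_i, c_i, oh_i * stride + ki, ow_i * stride + kj), out.grad)
            if padding:
                gx = gx[:, :, padding:Hp - padding, padding:Wp - padding]
            a._acc(gx)
        out._backward = bwd
        return out

    def upsample_bilinear2x(self):
        """2x bilinear upsampling with half-pixel centers (no corner alignment)."""
        a = self
        N, C, H, W = a.shape
        i0, i1, wi = _bilinear_axis(H)
        j0, j1, wj = _bilinear_axis(W)
        x = a.data
        top = (x[:, :, i0, :] * (1 - wi)[None, None, :, None]
               + x[:, :, i1, :] * wi[None, None, :, None])
        data = (top[:, :, :, j0] * (1 - wj)[None, None, None, :]
                + top[:, :, :, j1] * wj[None, None, None, :]).astype(x.dtype, copy=False)
        out = Tensor._make(data, (a,), None)

        def bwd():
            g = out.grad
            gtop = np.zeros((N, C, 2 * H, W), dtype=x.dtype)
            np.add.at(gtop, (slice(None), slice(None), slice(None), j0),
                      g * (1 - wj)[None, None, None, :])
            np.add.at(gtop, (slice(None), slice(None), slice(None), j1),
                      g * wj[None, None, None, :])
            gx = np.zeros_like(x)
            np.add.at(gx, (slice(None), slice(None), i0, slice(None)),
                      gtop * (1 - wi)[None, None, :, None])
            np.add.at(gx, (slice(None), slice(None), i1, slice(None)),
                      gtop * wi[None, None, :, None])
            a._acc(gx)
        out._backward = bwd
        return out


def _bilinear_axis(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source indices and weights for one axis of a 2x half-pixel upsample."""
    coords = (np.arange(2 * n, dtype=np.float64) + 0.5) / 2.0 - 0.5
    coords = np.clip(coords, 0, n - 1)
    lo = np.floor(coords).astype(np.int64)
    hi = np.minimum(lo + 1, n - 1)
    w = (coords - lo)
    return lo, hi, w


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * data.ndim
            idx[axis] = slice(int(lo), int(hi))
            t._acc(out.grad[tuple(idx)])
    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    return concat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors], axis=axis)
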