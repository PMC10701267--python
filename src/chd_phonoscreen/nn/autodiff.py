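"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates
gradients through the recorded graph.  Only the operations the LCACNN
classifier needs are provided; convolutions and pooling are primitives
with hand-written adjoints (convolution is computed as a sum of
kernel-offset products, which keeps both passes as plain einsums).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * (other ** -1.0)
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward():
            self._accum(out.grad * p * self.data ** (p - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward():
            self._accum(out.grad * (self.data > 0))

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward():
            self._accum(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward():
            self._accum(out.grad / self.data)

        out = self._make(out_data, (self,), backward)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    # -- reductions and shape ops ----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else axis
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward():
            self._accum(out.grad.reshape(self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            self._accum(out.grad.transpose(inv))

        out = self._make(out_data, (self,), backward)
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out = self._make(out_data, (self,), backward)
        return out

    # -- convolution / pooling primitives --------------------------------

    def conv2d(self, w: "Tensor", b: "Tensor" = None):
        """Standard 2-D convolution, stride 1, same (zero) padding.

        self: (N, C, H, W); w: (O, C, kh, kw) with odd kh, kw.
        """
        n, c, h, wd = self.data.shape
        o, c2, kh, kw = w.data.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd")
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        out_data = np.zeros((n, o, h, wd))
        for u in range(kh):
            for v in range(kw):
                out_data += np.einsum("oc,nchw->nohw", w.data[:, :, u, v],
                                      xp[:, :, u:u + h, v:v + wd], optimize=True)
        if b is not None:
            out_data += b.data[None, :, None, None]

        def backward():
            g = out.grad
            dxp = np.zeros_like(xp)
            dw = np.zeros_like(w.data)
            for u in range(kh):
                for v in range(kw):
                    sl = xp[:, :, u:u + h, v:v + wd]
                    dw[:, :, u, v] = np.einsum("nohw,nchw->oc", g, sl, optimize=True)
                    dxp[:, :, u:u + h, v:v + wd] += np.einsum(
                        "oc,nohw->nchw", w.data[:, :, u, v], g, optimize=True)
            self._accum(dxp[:, :, ph:ph + h, pw:pw + wd])
            w._accum(dw)
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3)))

        parents = (self, w) if b is None else (self, w, b)
        out = self._make(out_data, parents, backward)
        return out

    def depthwise_conv2d(self, k: "Tensor"):
        """Per-channel 2-D convolution, stride 1, same padding.

        self: (N, C, H, W); k: (C, kh, kw) with odd kh, kw.
        """
        n, c, h, wd = self.data.shape
        c2, kh, kw = k.data.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd")
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        out_data = np.zeros((n, c, h, wd))
        for u in range(kh):
            for v in range(kw):
                out_data += k.data[None, :, u, v, None, None] * xp[:, :, u:u + h, v:v + wd]

        def backward():
            g = out.grad
            dxp = np.zeros_like(xp)
            dk = np.zeros_like(k.data)
            for u in range(kh):
                for v in range(kw):
                    sl = xp[:, :, u:u + h, v:v + wd]
                    dk[:, u, v] = (g * sl).sum(axis=(0, 2, 3))
                    dxp[:, :, u:u + h, v:v + wd] += k.data[None, :, u, v, None, None] * g
            self._accum(dxp[:, :, ph:ph + h, pw:pw + wd])
            k._accum(dk)

        out = self._make(out_data, (self, k), backward)
        return out

    def max_pool2d(self, size: int):
        """Non-overlapping max pooling; ties share the gradient equally."""
        n, c, h, w = self.data.shape
        if h % size or w % size:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {size}")
        ho, wo = h // size, w // size
        r = self.data.reshape(n, c, ho, size, wo, size)
        out_data = r.max(axis=(3, 5))

        def backward():
            mask = (r == out_data[:, :, :, None, :, None])
            counts = mask.sum(axis=(3, 5), keepdims=True)
            g = mask * (out.grad[:, :, :, None, :, None] / counts)
            self._accum(g.reshape(n, c, h, w))

        out = self._make(out_data, (self,), backward)
        return out

    def avg_pool2d(self, size: int):
        """Non-overlapping average pooling."""
        n, c, h, w = self.data.shape
        if h % size or w % size:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {size}")
        ho, wo = h // size, w // size
        r = self.data.reshape(n, c, ho, size, wo, size)
        out_data = r.mean(axis=(3, 5))

        def backward():
            g = out.grad[:, :, :, None, :, None] / (size * size)
            self._accum(np.broadcast_to(g, r.shape).reshape(n, c, h, w))

        out = self._make(out_data, (self,), backward)
        return out

    def pad_edge2d(self, ph: int, pw: int):
        """Replicate-pad the two trailing spatial axes (bottom/right only)."""
        if ph == 0 and pw == 0:
            return self
        out_data = np.pad(self.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        n, c, h, w = self.data.shape

        def backward():
            g = out.grad.copy()
            if pw:
                g[:, :, :, w - 1] += g[:, :, :, w:].sum(axis=3)
                g = g[:, :, :, :w]
            if ph:
                g[:, :, h - 1, :] += g[:, :, h:, :].sum(axis=2)
                g = g[:, :, :h, :]
            self._accum(g)

        out = self._make(out_data, (self,), backward)
        return out


def concat(tensors: list, axis: int) -> Tensor:
    """Concatenate tensors along an axis."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward():
        offset = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * out_data.ndim
            idx[axis] = slice(offset, offset + s)
            t._accum(out.grad[tuple(idx)])
            offset += s

    out = Tensor(out_data)
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
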