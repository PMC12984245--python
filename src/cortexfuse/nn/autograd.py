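"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ndarray, records the
operations applied to it, and ``backward()`` runs the chain rule through the
recorded graph. Only the operations the segmentation network and its losses
need are implemented (elementwise arithmetic, matmul, reductions, 2-D
convolution, pooling, padding, nearest-neighbour upsampling, slicing).

Float32 is the working dtype for speed; float64 inputs are preserved so the
numeric gradient checks in the test suite can run at full precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -------------------------------------------------------------- helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g / (2.0 * out_data))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, self.data, slope * self.data), (self,), backward)

    def relu(self):
        return self.leaky_relu(0.0)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the un-clamped region only."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accumulate(gx)

        return self._make(self.data[idx], (self,), backward)

    def pad2d(self, pad: int, mode: str = "constant"):
        """Pad the two trailing (spatial) axes of an NCHW tensor."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width, mode=mode)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

        def backward(g):
            if mode == "constant":
                self._accumulate(g[sl])
            else:  # reflect: fold the padded gradient back onto its sources
                gx = np.zeros_like(self.data)
                h, w = self.shape[-2], self.shape[-1]
                rows = np.pad(np.arange(h), pad, mode=mode)
                cols = np.pad(np.arange(w), pad, mode=mode)
                np.add.at(gx, (Ellipsis, rows[:, None], cols[None, :]), g)
                self._accumulate(gx)

        return self._make(out_data, (self,), backward)

    def crop2d(self, top: int, left: int, height: int, width: int):
        return self[..., top:top + height, left:left + width]

    # --------------------------------------------------------------- spatial
    def upsample2x(self):
        """Nearest-neighbour x2 upsampling of an NCHW tensor."""
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)

        def backward(g):
            s = g.shape
            gg = g.reshape(*s[:-2], s[-2] // 2, 2, s[-1] // 2, 2).sum(axis=(-3, -1))
            self._accumulate(gg)

        return self._make(out_data, (self,), backward)

    def avg_pool2x2(self):
        n, c, h, w = self.shape
        assert h % 2 == 0 and w % 2 == 0, "avg_pool2x2 needs even spatial dims"
        out_data = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward(g):
            gg = g.repeat(2, axis=-2).repeat(2, axis=-1) * 0.25
            self._accumulate(gg)

        return self._make(out_data, (self,), backward)

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation, NCHW input, OIHW weight."""
        x = self.pad2d(padding) if padding else self
        xd = x.data
        n, cin, h, w = xd.shape
        cout, cin2, kh, kw = weight.shape
        if cin != cin2:
            raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin2}")
        ho = (h - kh) // stride + 1
        wo = (w - kw) // stride + 1
        cols = np.empty((n, cin, kh * kw, ho * wo), dtype=xd.dtype)
        for i in range(kh):
            for j in range(kw):
                patch = xd[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                cols[:, :, i * kw + j, :] = patch.reshape(n, cin, -1)
        cols = cols.reshape(n, cin * kh * kw, ho * wo)
        w2 = weight.data.reshape(cout, -1)
        out_data = np.matmul(w2, cols).reshape(n, cout, ho, wo)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)

        parents = (x, weight) + ((bias,) if bias is not None else ())

        def backward(g):
            g2 = g.reshape(n, cout, ho * wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                gw = np.einsum("nol,nkl->ok", g2, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gcols = np.matmul(w2.T, g2)  # n, K, L
                gcols = gcols.reshape(n, cin, kh * kw, ho, wo)
                gx = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + stride * ho:stride,
                           j:j + stride * wo:stride] += gcols[:, :, i * kw + j]
                x._accumulate(gx)

        return x._make(out_data, parents, backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))

    def backward(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    if req:
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))

    def backward(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, k, axis=axis))

    if req:
        out._backward = backward
    return out
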