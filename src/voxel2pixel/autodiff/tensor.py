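"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the reconstruction networks need:
broadcast-aware arithmetic, matmul, strided 2-D (transposed) convolution,
pointwise nonlinearities, reductions, reshaping/concatenation and a
numerically stable binary cross-entropy on logits. Everything is float64.

Gradient correctness is established by central finite differences in the
test suite rather than asserted per-op here.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "bce_with_logits", "set_default_dtype",
           "get_default_dtype", "using_dtype"]

_DTYPE = np.float64


def set_default_dtype(dtype):
    """Set the dtype newly created tensors are cast to (float64 default;
    float32 roughly halves training time at GAN-irrelevant precision cost)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype)


def get_default_dtype():
    return _DTYPE


@contextlib.contextmanager
def using_dtype(dtype):
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- graph machinery -----------------------------------------------------
    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in prev if p.requires_grad))
        if req:
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long conv stacks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(g):
            self._accumulate(-g)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward if out.requires_grad else None
        return out

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,), None)

        def backward(g):
            self._accumulate(g * (self.data > 0))

        out._backward = backward if out.requires_grad else None
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = self._make(np.where(self.data > 0, self.data, slope * self.data), (self,), None)

        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = backward if out.requires_grad else None
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * (1.0 - y**2))

        out._backward = backward if out.requires_grad else None
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        out._backward = backward if out.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * y)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            self._accumulate(g / self.data)

        out._backward = backward if out.requires_grad else None
        return out

    def abs(self):
        out = self._make(np.abs(self.data), (self,), None)

        def backward(g):
            self._accumulate(g * np.sign(self.data))

        out._backward = backward if out.requires_grad else None
        return out

    def sqrt_safe(self, eps: float = 1e-12):
        """Exact sqrt forward; gradient clamped near zero so sqrt(0) stays finite."""
        y = np.sqrt(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * 0.5 / np.sqrt(np.maximum(self.data, eps)))

        out._backward = backward if out.requires_grad else None
        return out

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def transpose(self, *axes):
        out = self._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        out._backward = backward if out.requires_grad else None
        return out

    # -- convolution ----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """Cross-correlation of [N,C,H,W] with weight [O,C,k,k].

        Decomposed over kernel positions: k*k batched matmuls on strided
        views, which keeps every heavy operation inside BLAS.
        """
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        O, _, k, _ = w.shape
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (xp.shape[2] - k) // s + 1
        Wo = (xp.shape[3] - k) // s + 1
        L = Ho * Wo
        y = np.zeros((N, O, L), dtype=x.dtype)
        xs_flat = []
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s].reshape(N, C, L)
                xs_flat.append(xs)
                y += np.matmul(w[:, :, ki, kj], xs)
        y = y.reshape(N, O, Ho, Wo)
        if bias is not None:
            y = y + bias.data.reshape(1, O, 1, 1)
        prev = (self, weight) + ((bias,) if bias is not None else ())
        out = self._make(y, prev, None)

        def backward(g):
            g2 = g.reshape(N, O, L)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            gxp = np.zeros_like(xp) if self.requires_grad else None
            gw = np.zeros_like(w) if weight.requires_grad else None
            for ki in range(k):
                for kj in range(k):
                    xs = xs_flat[ki * k + kj]
                    if weight.requires_grad:
                        gw[:, :, ki, kj] = np.tensordot(g2, xs, axes=([0, 2], [0, 2]))
                    if self.requires_grad:
                        dxs = np.matmul(w[:, :, ki, kj].T, g2)  # [N,C,L]
                        gxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += \
                            dxs.reshape(N, C, Ho, Wo)
            if weight.requires_grad:
                weight._accumulate(gw)
            if self.requires_grad:
                self._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        out._backward = backward if out.requires_grad else None
        return out

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0):
        """Transposed convolution; weight [C_in, C_out, k, k].

        Forward is the input-gradient of a conv with the same weight, so
        output size is (H-1)*stride + k - 2*padding.
        """
        x, w = self.data, weight.data
        N, Ci, H, W = x.shape
        _, Co, k, _ = w.shape
        s, p = stride, padding
        Ho = (H - 1) * s + k - 2 * p
        Wo = (W - 1) * s + k - 2 * p
        L = H * W
        x2 = x.reshape(N, Ci, L)
        yp = np.zeros((N, Co, Ho + 2 * p, Wo + 2 * p), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                contrib = np.matmul(w[:, :, ki, kj].T, x2).reshape(N, Co, H, W)
                yp[:, :, ki:ki + s * H:s, kj:kj + s * W:s] += contrib
        y = yp[:, :, p:p + Ho, p:p + Wo] if p else yp
        if bias is not None:
            y = y + bias.data.reshape(1, Co, 1, 1)
        prev = (self, weight) + ((bias,) if bias is not None else ())
        out = self._make(np.ascontiguousarray(y), prev, None)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
            gx = np.zeros((N, Ci, L), dtype=x.dtype) if self.requires_grad else None
            gw = np.zeros_like(w) if weight.requires_grad else None
            for ki in range(k):
                for kj in range(k):
                    gs = gp[:, :, ki:ki + s * H:s, kj:kj + s * W:s].reshape(N, Co, L)
                    if self.requires_grad:
                        gx += np.matmul(w[:, :, ki, kj], gs)
                    if weight.requires_grad:
                        gw[:, :, ki, kj] = np.tensordot(x2, gs, axes=([0, 2], [0, 2]))
            if self.requires_grad:
                self._accumulate(gx.reshape(N, Ci, H, W))
            if weight.requires_grad:
                weight._accumulate(gw)

        out._backward = backward if out.requires_grad else None
        return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(gpart)

        out._backward = backward
    return out


def bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy of logits against a constant label in {0, 1}.

    Stable form: softplus(x) - target*x, with softplus via logaddexp.
    """
    x = logits.data
    val = np.logaddexp(0.0, x) - target * x
    out = Tensor(val.mean(), requires_grad=logits.requires_grad,
                 _prev=(logits,) if logits.requires_grad else ())
    if logits.requires_grad:
        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
            logits._accumulate(g * (sig - target) / x.size)

        out._backward = backward
    return out
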