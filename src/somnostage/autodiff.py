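"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine, just large enough to express and train the
sleep-staging network on a CPU: broadcast-aware elementwise arithmetic,
batched matmul, reductions, shape ops, fused layer-norm / softmax /
cross-entropy, causal 1-D convolution and dilated "same" 2-D convolution.

Everything is float64.  Gradients accumulate into ``Tensor.grad`` after
calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "relu",
    "sigmoid",
    "softmax",
    "layer_norm",
    "cross_entropy_logits",
    "index_select",
    "causal_conv1d",
    "conv2d_same",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

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

    # -- autodiff core --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- transcendental -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)


# -- free functions ---------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable affine terms."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + bias.data

    def backward(g):
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if x.requires_grad:
            gx = g * gain.data
            # d/dx of (x - mu) * inv with mu, inv functions of x
            t1 = gx
            t2 = gx.mean(axis=-1, keepdims=True)
            t3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (t1 - t2 - t3))

    return Tensor._make(out_data, (x, gain, bias), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Fused for numerical stability; backward is (softmax - onehot) / N.
    """
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(g * p / n)

    return Tensor._make(loss, (logits,), backward)


def index_select(x: Tensor, idx: np.ndarray, axis: int = 0) -> Tensor:
    """Gather slices along ``axis``; backward scatter-adds."""
    idx = np.asarray(idx)
    out_data = np.take(x.data, idx, axis=axis)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(np.moveaxis(gx, axis, 0), idx, np.moveaxis(g, axis, 0))
            x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def causal_conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Causal 1-D convolution along the token axis.

    ``x`` has shape (batch, T, C_in); ``weight`` has shape (k, C_in, C_out).
    The input is left-padded with k-1 zeros so output step t depends only on
    input steps <= t and the output keeps length T.
    """
    k = weight.data.shape[0]
    T = x.data.shape[1]
    xp = np.pad(x.data, ((0, 0), (k - 1, 0), (0, 0)))
    # cols[b, t, i, c_in] = xp[b, t + i, c_in]  (i = tap index, oldest first)
    cols = np.stack([xp[:, i : i + T, :] for i in range(k)], axis=2)
    out_data = np.einsum("btic,ico->bto", cols, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("btic,bto->ico", cols, g, optimize=True)
            weight._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            gcols = np.einsum("bto,ico->btic", g, weight.data, optimize=True)
            for i in range(k):
                gxp[:, i : i + T, :] += gcols[:, :, i, :]
            x._accum(gxp[:, k - 1 :, :])

    return Tensor._make(out_data, parents, backward)


def _shift2d(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift the last two axes by (dr, dc), zero-filling; out[r, c] = a[r+dr, c+dc]."""
    H, W = a.shape[-2], a.shape[-1]
    out = np.zeros_like(a)
    rs_src = slice(max(dr, 0), H + min(dr, 0))
    cs_src = slice(max(dc, 0), W + min(dc, 0))
    rs_dst = slice(max(-dr, 0), H + min(-dr, 0))
    cs_dst = slice(max(-dc, 0), W + min(-dc, 0))
    out[..., rs_dst, cs_dst] = a[..., rs_src, cs_src]
    return out


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Single-channel 3x3 (or kxk) 2-D convolution with "same" zero padding.

    ``x`` has shape (..., H, W); ``weight`` has shape (k, k).  Implemented as a
    sum of k*k zero-padded shifts, which also yields a simple exact backward.
    """
    k = weight.data.shape[0]
    c = k // 2
    out_data = np.zeros_like(x.data)
    for i in range(k):
        for j in range(k):
            out_data += weight.data[i, j] * _shift2d(x.data, (i - c) * dilation, (j - c) * dilation)
    if bias is not None:
        out_data = out_data + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(np.asarray(g.sum()).reshape(bias.data.shape))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for i in range(k):
                for j in range(k):
                    gw[i, j] = (g * _shift2d(x.data, (i - c) * dilation, (j - c) * dilation)).sum()
            weight._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for i in range(k):
                for j in range(k):
                    gx += weight.data[i, j] * _shift2d(g, -(i - c) * dilation, -(j - c) * dilation)
            x._accum(gx)

    return Tensor._make(out_data, parents, backward)
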