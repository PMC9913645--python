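"""A compact reverse-mode automatic differentiation engine on NumPy arrays.

Supports exactly the operations the network needs: broadcasting arithmetic,
matrix multiplication, reductions, shape manipulation, slicing/concatenation,
the ReLU/GELU nonlinearities, a numerically stable softmax, probability
clamping, a fused affine normalisation, and a strided channels-last 2-D
convolution (im2col + GEMM).  Gradients are accumulated on every tensor that
requires them; ``Tensor.backward`` walks the graph in reverse topological
order, releasing intermediate gradients as it goes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "affine_norm", "concat", "conv2d"]

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))
_SCALARS = (int, float, np.integer, np.floating)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (12 blocks)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g
            if node._parents:  # free intermediate grads; leaves keep theirs
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    # python scalars take a dedicated path so that numpy's weak promotion
    # keeps float32 graphs in float32
    def __add__(self, other):
        a = self
        if isinstance(other, _SCALARS):
            other = float(other)  # python floats promote weakly
            return self._node(a.data + other, (a,), lambda g: (g,))
        b = self._lift(other)

        def bwd(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return self._node(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._node(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, _SCALARS):
            return self + (-other)
        return self + (-self._lift(other))

    def __rsub__(self, other):
        neg = -self
        return neg + other if isinstance(other, _SCALARS) else self._lift(other) + neg

    def __mul__(self, other):
        a = self
        if isinstance(other, _SCALARS):
            other = float(other)
            return self._node(a.data * other, (a,), lambda g: (g * other,))
        b = self._lift(other)

        def bwd(g):
            return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

        return self._node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, _SCALARS):
            return self * (1.0 / other)
        b = self._lift(other)
        a = self

        def bwd(g):
            ga = _unbroadcast(g / b.data, a.shape)
            gb = _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
            return ga, gb

        return self._node(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        a = self

        def bwd(g):
            return (-g * other / (a.data * a.data),)

        if isinstance(other, _SCALARS):
            return self._node(float(other) / a.data, (a,), bwd)
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def bwd(g):
            return (g * p * a.data ** (p - 1.0),)

        return self._node(a.data**p, (a,), bwd)

    def sqrt(self):
        return self**0.5

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            bd, ad = b.data, a.data
            if bd.ndim == 1:
                ga = np.expand_dims(g, -1) * bd
            else:
                ga = g @ bd.swapaxes(-1, -2)
            if ad.ndim == 1:
                gb = np.expand_dims(ad, -1) * np.expand_dims(g, -2)
            else:
                gb = ad.swapaxes(-1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return self._node(a.data @ b.data, (a, b), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        a = self
        return self._node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], tuple):
            axes = axes[0]
        a = self
        inv = np.argsort(axes)
        return self._node(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            return (ga,)

        return self._node(a.data[idx], (a,), bwd)

    def broadcast_to(self, shape):
        a = self
        return self._node(
            np.broadcast_to(a.data, shape).copy(),
            (a,),
            lambda g: (_unbroadcast(g, a.shape),),
        )

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        a = self
        mask = a.data > 0
        return self._node(a.data * mask, (a,), lambda g: (g * mask,))

    def gelu(self):
        """Exact Gaussian-error-linear unit x * Phi(x)."""
        a = self
        phi_cdf = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))

        def bwd(g):
            pdf = np.exp(-0.5 * a.data * a.data) * _INV_SQRT2PI
            return (g * (phi_cdf + a.data * pdf),)

        return self._node(a.data * phi_cdf, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._node(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return self._node(np.log(a.data), (a,), lambda g: (g / a.data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclipped entries."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)
        return self._node(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

        return self._node(s, (a,), bwd)


def affine_norm(x: Tensor, gamma: Tensor, beta: Tensor, axes,
                eps: float = 1e-5, stats_out: list | None = None) -> Tensor:
    """Fused normalisation y = gamma * (x - mu) / sqrt(var + eps) + beta with
    mu/var (biased) computed over `axes`; gamma/beta must broadcast against x.

    Single graph node: used for both batch norm and layer norm to keep the
    training graph small.  When ``stats_out`` is given, (mu, var) are
    appended so callers can track running statistics without recomputing.
    """
    axes = axes if isinstance(axes, tuple) else (axes,)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    if stats_out is not None:
        stats_out.append((mu.reshape(-1), var.reshape(-1)))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def bwd(g):
        dgamma = _unbroadcast(g * xhat, gamma.shape)
        dbeta = _unbroadcast(g, beta.shape)
        gh = g * gamma.data
        dx = inv * (gh - gh.mean(axis=axes, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=axes, keepdims=True))
        return dx, dgamma, dbeta

    return Tensor._node(out_data, (x, gamma, beta), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._node(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def _im2col_nhwc(xp: np.ndarray, KH: int, KW: int, stride: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, (KH, KW), axis=(1, 2))[:, ::stride, ::stride]
    B, OH, OW, C = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        B * OH * OW, KH * KW * C)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col + GEMM, channels-last.

    x: (B, H, W, C), w: (F, C, KH, KW), b: (F,).  Zero padding.  The
    channels-last layout keeps every GEMM operand contiguous, so no output
    or gradient transposes are needed; the im2col matrix is cached for the
    weight-gradient GEMM and the input gradient is skipped when unused.
    """
    xd, wd = x.data, w.data
    B, H, W, C = xd.shape
    F, Cw, KH, KW = wd.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    xp = np.pad(xd, ((0, 0), (padding,) * 2, (padding,) * 2, (0, 0))) if padding else xd
    cols = _im2col_nhwc(xp, KH, KW, stride)
    wmat = np.ascontiguousarray(wd.transpose(2, 3, 1, 0)).reshape(KH * KW * C, F)
    out = cols @ wmat
    if b is not None:
        out = out + b.data
    OH = (xp.shape[1] - KH) // stride + 1
    OW = (xp.shape[2] - KW) // stride + 1
    out = out.reshape(B, OH, OW, F)

    def bwd(g):
        gmat = np.ascontiguousarray(g).reshape(B * OH * OW, F)
        gw = np.ascontiguousarray(
            (cols.T @ gmat).reshape(KH, KW, C, F).transpose(3, 2, 0, 1))
        gb = gmat.sum(axis=0) if b is not None else None
        gx = None
        if x.requires_grad:
            gwin = (gmat @ wmat.T).reshape(B, OH, OW, KH, KW, C)
            Hp, Wp = xp.shape[1], xp.shape[2]
            acc = np.zeros((B, Hp, Wp, C), dtype=g.dtype)
            for i in range(KH):
                for j in range(KW):
                    acc[:, i : i + OH * stride : stride,
                        j : j + OW * stride : stride, :] += gwin[:, :, :, i, j, :]
            if padding:
                acc = acc[:, padding : padding + H, padding : padding + W, :]
            gx = np.ascontiguousarray(acc)
        parents_grads = [gx, gw]
        if b is not None:
            parents_grads.append(gb)
        return tuple(parents_grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out, parents, bwd)
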