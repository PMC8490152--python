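"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the sequence-to-profile network: a small
tape-based engine in the style of the early autograd libraries, with exactly
the operations the model needs (broadcast-aware arithmetic, matmul,
reductions, indexing, 1-D unfolding for convolutions, and the relative-shift
gather used by relative positional attention).  Gradients produced here are
checked against central finite differences in the test suite.

Only ``Tensor`` leaves created with ``requires_grad=True`` (parameters,
or inputs being attributed) receive a ``.grad`` after ``backward()``.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Optional

import numpy as np
from scipy import special as _sp

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / augmentation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------

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
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def astype(self, dtype) -> "Tensor":
        src = self.dtype

        def bw(g):
            return (g.astype(src),)

        return Tensor._op(self.data.astype(dtype), (self,), bw)

    # -- backward -------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if p.requires_grad:
                        stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            # release the tape node (and the arrays its closure captured)
            # as soon as its gradient has been propagated; the graph is
            # single-use, as in most define-by-run engines
            node._backward = None
            node._parents = ()

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return Tensor._op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            return (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape))

        return Tensor._op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            return (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
            )

        return Tensor._op(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            return (g * p * np.power(a.data, p - 1),)

        return Tensor._op(np.power(a.data, p), (a,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = a.data @ b.data

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._op(out, (a, b), bw)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            return (g.reshape(old),)

        return Tensor._op(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            return (g.transpose(inv),)

        return Tensor._op(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, key):
        a = self
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple) and all(isinstance(k, (int, slice, type(Ellipsis), type(None))) for k in key)
        )

        def bw(g):
            out = np.zeros(a.shape, dtype=g.dtype)
            if basic:
                out[key] += g  # basic indexing never aliases; fast path
            else:
                np.add.at(out, key, g)
            return (out,)

        return Tensor._op(a.data[key], (a,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[ax] for ax in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def sqsum(self, axis=None, keepdims=False):
        """Sum of squares along an axis, without materializing x*x."""
        a = self

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (2.0 * a.data * gg,)

        return Tensor._op((a.data * a.data).sum(axis=axis, keepdims=keepdims), (a,), bw)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            return (g * out,)

        return Tensor._op(out, (self,), bw)

    def log(self):
        a = self

        def bw(g):
            return (g / a.data,)

        return Tensor._op(np.log(a.data), (a,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            return (g * 0.5 / out,)

        return Tensor._op(out, (self,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            return (g * mask,)

        return Tensor._op(np.where(mask, a.data, 0), (a,), bw)

    def sigmoid(self):
        out = _sp.expit(self.data)

        def bw(g):
            return (g * out * (1 - out),)

        return Tensor._op(out, (self,), bw)

    def softplus(self):
        """log(1 + e^x), computed stably; used for positive-rate outputs."""
        a = self
        out = np.logaddexp(0.0, a.data).astype(a.data.dtype)

        def bw(g):
            return (g * _sp.expit(a.data),)

        return Tensor._op(out, (a,), bw)

    def gelu(self):
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + _sp.erf(x * 0.7071067811865476))  # Phi(x), dtype-preserving

        def bw(g):
            pdf = np.exp(-0.5 * x * x) * 0.3989422804014327  # phi(x)
            return (g * (cdf + x * pdf),)

        return Tensor._op(x * cdf, (a,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- free functions ------------------------------------------------------------


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def pad1d(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad axis 1 of a (B, L, C) tensor."""
    a = x
    L = a.shape[1]

    def bw(g):
        return (g[:, left : left + L, :],)

    width = [(0, 0)] * a.ndim
    width[1] = (left, right)
    return Tensor._op(np.pad(a.data, width), (a,), bw)


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """(B, L, C) -> (B, L - K + 1, K, C) sliding windows (valid)."""
    a = x
    B, L, C = a.shape
    K = kernel
    Lo = L - K + 1
    win = np.lib.stride_tricks.sliding_window_view(a.data, K, axis=1)  # (B, Lo, C, K)
    out = np.ascontiguousarray(np.swapaxes(win, 2, 3))  # (B, Lo, K, C)

    def bw(g):
        gx = np.zeros((B, L, C), dtype=g.dtype)
        for k in range(K):
            gx[:, k : k + Lo, :] += g[:, :, k, :]
        return (gx,)

    return Tensor._op(out, (a,), bw)


def conv1d_same(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """'Same'-padded 1-D convolution: (B, L, Cin) * (K, Cin, Cout) -> (B, L, Cout).

    Computed as a sum over kernel taps of shifted matmuls, which avoids
    materializing the unfolded (B, L, K, Cin) window tensor.
    """
    B, L, Cin = x.shape
    K = w.shape[0]
    left = (K - 1) // 2
    xd, wd = x.data, w.data
    out = np.zeros((B, L, w.shape[2]), dtype=xd.dtype)
    # tap k reads input positions (i + k - left)
    for k in range(K):
        lo_in, hi_in = max(0, k - left), min(L, L + k - left)
        lo_out, hi_out = max(0, left - k), min(L, L + left - k)
        out[:, lo_out:hi_out] += xd[:, lo_in:hi_in] @ wd[k]
    if b is not None:
        out += b.data

    def bw(g):
        gx = np.zeros_like(xd) if x.requires_grad else None
        gw = np.zeros_like(wd) if w.requires_grad else None
        for k in range(K):
            lo_in, hi_in = max(0, k - left), min(L, L + k - left)
            lo_out, hi_out = max(0, left - k), min(L, L + left - k)
            gs = g[:, lo_out:hi_out]
            if gx is not None:
                gx[:, lo_in:hi_in] += gs @ wd[k].T
            if gw is not None:
                gw[k] = np.tensordot(xd[:, lo_in:hi_in], gs, axes=([0, 1], [0, 1]))
        gb = g.sum(axis=(0, 1)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._op(out, parents, bw)


def rel_shift(x: Tensor, L: int) -> Tensor:
    """Gather relative-position terms into a square attention bias.

    ``x`` has shape (..., L, 2L-1) where the last axis is indexed by relative
    distance d = i - j laid out as d = -(L-1) ... (L-1) at positions 0 ... 2L-2.
    Returns y with y[..., i, j] = x[..., i, (L-1) + (i - j)].
    """
    a = x
    if a.shape[-2] != L or a.shape[-1] != 2 * L - 1:
        raise ValueError(f"rel_shift expects (..., {L}, {2 * L - 1}), got {a.shape}")
    # row i of the output reads x[..., i, i : i + L] reversed (j = 0..L-1
    # maps to distance index (L-1) + i - j); per-row slicing beats a fancy
    # gather/scatter by a wide margin at transformer lengths
    out = np.empty(a.shape[:-1] + (L,), dtype=a.data.dtype)
    for i in range(L):
        out[..., i, :] = a.data[..., i, i : i + L][..., ::-1]

    def bw(g):
        gx = np.zeros(a.shape, dtype=g.dtype)
        for i in range(L):
            gx[..., i, i : i + L] += g[..., i, ::-1]
        return (gx,)

    return Tensor._op(out, (a,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def stack_mean(tensors) -> Tensor:
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out / len(tensors)
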