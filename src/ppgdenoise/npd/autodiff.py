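"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

This is deliberately small: just the tensor operations the 1D texture
transformer needs (broadcast arithmetic, batched matmul, ReLU, 1D
convolution, patch unfold/fold with overlap averaging, index gathers, clip,
and reductions). Everything is float64 and single-threaded, so forward and
backward passes are bitwise deterministic.

Gradients follow the standard conventions: broadcasting sums the gradient
over broadcast axes; ``clip`` passes gradient only strictly inside its
bounds; integer index maps (argmax results) are treated as constants.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "transpose", "concat",
    "relu", "absval", "sqrt", "clip", "sum_", "mean_", "power",
    "conv1d", "unfold1d", "fold1d", "gather_patches", "gather_scores",
    "l2normalize",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _backward: Optional[Callable[[], None]] = None,
                 _parents: Sequence["Tensor"] = ()) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._parents = tuple(_parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
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
                    stack.append((p, False))

        visit(self)
        self.accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # The backward closures reference their own output tensors, forming
        # reference cycles; break them so buffers are freed by refcounting
        # (a graph is only ever differentiated once).
        for node in topo:
            node._backward = None
            node._parents = ()
            if node is not self and node.requires_grad is False:
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[Tensor], Callable[[], None]]) -> Tensor:
    req = _needs(*parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


# -- arithmetic -------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(out.grad, b.shape))
        return fn

    return _make(a.data + b.data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(_as_tensor(b)))


def neg(a: Tensor) -> Tensor:
    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(-out.grad)
        return fn

    return _make(-a.data, (a,), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(out.grad * a.data, b.shape))
        return fn

    return _make(a.data * b.data, (a, b), bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(_unbroadcast(out.grad / b.data, a.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(-out.grad * a.data / (b.data ** 2),
                                          b.shape))
        return fn

    return _make(a.data / b.data, (a, b), bwd)


def power(a: Tensor, p: float) -> Tensor:
    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(out.grad * p * a.data ** (p - 1))
        return fn

    return _make(a.data ** p, (a,), bwd)


def sqrt(a: Tensor) -> Tensor:
    y = np.sqrt(a.data)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(out.grad * 0.5 / np.sqrt(a.data))
        return fn

    return _make(y, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """(Batched) matrix product via ``np.matmul`` semantics."""
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                ga = np.matmul(out.grad, np.swapaxes(b.data, -1, -2))
                a.accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), out.grad)
                b.accumulate(_unbroadcast(gb, b.shape))
        return fn

    return _make(np.matmul(a.data, b.data), (a, b), bwd)


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    inv = np.argsort(axes)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(np.transpose(out.grad, inv))
        return fn

    return _make(np.transpose(a.data, axes), (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(out: Tensor):
        def fn():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(ts, parts):
                if t.requires_grad:
                    t.accumulate(g)
        return fn

    return _make(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)


# -- nonlinearities and reductions ------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(out.grad * mask)
        return fn

    return _make(a.data * mask, (a,), bwd)


def absval(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(out.grad * sign)
        return fn

    return _make(np.abs(a.data), (a,), bwd)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    inside = (a.data > lo) & (a.data < hi)

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(out.grad * inside)
        return fn

    return _make(np.clip(a.data, lo, hi), (a,), bwd)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bwd(out: Tensor):
        def fn():
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(g, a.shape).copy())
        return fn

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)


def mean_(a: Tensor) -> Tensor:
    n = a.data.size

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(np.broadcast_to(out.grad / n, a.shape).copy())
        return fn

    return _make(np.array(a.data.mean()), (a,), bwd)


# -- structured signal ops ---------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'same' 1D convolution (cross-correlation) with zero padding.

    ``x``: (B, Cin, L); ``w``: (Cout, Cin, k) with odd k; ``b``: (Cout,).
    """
    B, Cin, L = x.data.shape
    Cout, Cin2, k = w.data.shape
    assert Cin == Cin2 and k % 2 == 1
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # patches: (B, L, Cin*k)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    patches = win.transpose(0, 2, 1, 3).reshape(B, L, Cin * k)
    w2 = w.data.reshape(Cout, Cin * k)
    y = patches @ w2.T + b.data  # (B, L, Cout)
    y = y.transpose(0, 2, 1)

    def bwd(out: Tensor):
        def fn():
            g = out.grad.transpose(0, 2, 1)  # (B, L, Cout)
            if b.requires_grad:
                b.accumulate(g.sum(axis=(0, 1)))
            if w.requires_grad:
                gw2 = np.einsum("blo,blp->op", g, patches)
                w.accumulate(gw2.reshape(Cout, Cin, k))
            if x.requires_grad:
                gp = g @ w2  # (B, L, Cin*k)
                gp = gp.reshape(B, L, Cin, k)
                gxp = np.zeros((B, Cin, L + 2 * pad))
                for j in range(k):
                    gxp[:, :, j:j + L] += gp[:, :, :, j].transpose(0, 2, 1)
                x.accumulate(gxp[:, :, pad:pad + L])
        return fn

    return _make(y, (x, w, b), bwd)


def unfold1d(x: Tensor, patch: int, stride: int = 1) -> Tensor:
    """Extract overlapping patches: (B, C, L) -> (B, N, C*patch)."""
    B, C, L = x.data.shape
    if patch > L:
        raise ValueError("patch longer than the feature length")
    n = (L - patch) // stride + 1
    idx = (np.arange(n)[:, None] * stride + np.arange(patch)[None, :])  # (N, p)
    patches = x.data[:, :, idx]              # (B, C, N, p)
    out_data = patches.transpose(0, 2, 1, 3).reshape(B, n, C * patch)

    def bwd(out: Tensor):
        def fn():
            if not x.requires_grad:
                return
            g = out.grad.reshape(B, n, C, patch).transpose(0, 2, 1, 3)
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), idx), g)
            x.accumulate(gx)
        return fn

    return _make(out_data, (x,), bwd)


def _fold_counts(n: int, patch: int, stride: int, out_len: int) -> np.ndarray:
    counts = np.zeros(out_len)
    idx = np.arange(n)[:, None] * stride + np.arange(patch)[None, :]
    np.add.at(counts, idx.ravel(), 1.0)
    return counts


def fold1d(patches: Tensor, channels: int, patch: int, stride: int = 1) -> Tensor:
    """Overlap-average patches back to a signal: (B, N, C*patch) -> (B, C, L)
    with ``L = (N-1)*stride + patch``. Positions covered by several patches
    take the mean of their contributions."""
    B, n, cp = patches.data.shape
    assert cp == channels * patch
    out_len = (n - 1) * stride + patch
    idx = np.arange(n)[:, None] * stride + np.arange(patch)[None, :]  # (N, p)
    counts = _fold_counts(n, patch, stride, out_len)
    p4 = patches.data.reshape(B, n, channels, patch).transpose(0, 2, 1, 3)
    acc = np.zeros((B, channels, out_len))
    np.add.at(acc, (slice(None), slice(None), idx), p4)
    y = acc / counts

    def bwd(out: Tensor):
        def fn():
            if not patches.requires_grad:
                return
            g = out.grad / counts           # (B, C, L)
            gp = g[:, :, idx]               # (B, C, N, p)
            patches.accumulate(
                gp.transpose(0, 2, 1, 3).reshape(B, n, channels * patch))
        return fn

    return _make(y, (patches,), bwd)


def gather_patches(v: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of a patch tensor by an integer map: ``out[b, i, :] =
    v[b, index[b, i], :]``. The index map is a constant."""
    B, Nk, D = v.data.shape
    index = np.asarray(index)
    if index.min() < 0 or index.max() >= Nk:
        raise IndexError("hard-attention index out of range")
    out_data = np.take_along_axis(v.data, index[:, :, None], axis=1)

    def bwd(out: Tensor):
        def fn():
            if not v.requires_grad:
                return
            gv = np.zeros_like(v.data)
            np.add.at(gv, (np.arange(B)[:, None], index, slice(None)), out.grad)
            v.accumulate(gv)
        return fn

    return _make(out_data, (v,), bwd)


def gather_scores(rel: Tensor, index: np.ndarray) -> Tensor:
    """``out[b, i] = rel[b, i, index[b, i]]`` (soft-attention scores)."""
    B, Nq, Nk = rel.data.shape
    out_data = np.take_along_axis(rel.data, index[:, :, None], axis=2)[:, :, 0]

    def bwd(out: Tensor):
        def fn():
            if not rel.requires_grad:
                return
            g = np.zeros_like(rel.data)
            np.put_along_axis(g, index[:, :, None], out.grad[:, :, None], axis=2)
            rel.accumulate(g)
        return fn

    return _make(out_data, (rel,), bwd)


def l2normalize(a: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Normalize along an axis to unit Euclidean norm (composed primitives)."""
    sq = mul(a, a)
    norm = sqrt(add(sum_(sq, axis=axis, keepdims=True), Tensor(eps)))
    return div(a, norm)
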