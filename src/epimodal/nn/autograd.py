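"""A compact reverse-mode automatic differentiation core on numpy arrays.

Tensors form a tape: each operation records its parents and a closure that
accumulates gradients into them.  ``Tensor.backward()`` runs the tape in
reverse topological order.  The primitive set is exactly what the sequence,
structure and Siamese models need: broadcasting arithmetic, matmul, the
usual nonlinearities, reductions, reshaping/concatenation, row gather,
1D convolution and max pooling, and multiplication by a constant sparse
matrix (the GCN propagation step).

All primitives are gradient-checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph mechanics ----------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents, backward):
    req = _needs(*parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# -- arithmetic --------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def spmm(a_const: sp.spmatrix, h: Tensor) -> Tensor:
    """Multiply by a constant sparse matrix: out = A @ H (A carries no grad)."""
    a_csr = a_const.tocsr()
    out_data = np.asarray(a_csr @ h.data)

    def backward(g):
        if h.requires_grad:
            h._accumulate(np.asarray(a_csr.T @ g))

    return _make(out_data, (h,), backward)


# -- nonlinearities ----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - out_data**2))

    return _make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward(g):
        x._accumulate(g / x.data)

    return _make(out_data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g):
        x._accumulate(g * out_data)

    return _make(out_data, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes only where unclipped."""
    out_data = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def abs_(x: Tensor) -> Tensor:
    out_data = np.abs(x.data)
    sign = np.sign(x.data)

    def backward(g):
        x._accumulate(g * sign)

    return _make(out_data, (x,), backward)


def square(x: Tensor) -> Tensor:
    out_data = x.data**2

    def backward(g):
        x._accumulate(g * 2.0 * x.data)

    return _make(out_data, (x,), backward)


# -- reductions & shaping ----------------------------------------------------

def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape))

    return _make(out_data, (x,), backward)


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(sum_(x, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(out_data, (x,), backward)


def transpose(x: Tensor, axes=None) -> Tensor:
    out_data = x.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        x._accumulate(g.transpose(inv))

    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def getitem(x: Tensor, key) -> Tensor:
    out_data = x.data[key]

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, key, g)
        x._accumulate(full)

    return _make(out_data, (x,), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows by integer index with scatter-add backward."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accumulate(full)

    return _make(out_data, (x,), backward)


# -- convolution & pooling ---------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1D cross-correlation.

    x: (N, C, L); w: (F, C, K); b: (F,) -> out (N, F, L-K+1).
    """
    N, C, L = x.data.shape
    F, Cw, K = w.data.shape
    if C != Cw:
        raise ValueError(f"conv1d channel mismatch: input {C}, kernel {Cw}")
    if K > L:
        raise ValueError(f"kernel size {K} exceeds input length {L}")
    # patches: (N, C, L_out, K) via stride tricks, no copy
    patches = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)
    out_data = np.einsum("nclk,fck->nfl", patches, w.data, optimize=True) + b.data[None, :, None]

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accumulate(np.einsum("nclk,nfl->fck", patches, g, optimize=True))
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            # scatter each output position's contribution back over its K-window
            gp = np.einsum("nfl,fck->nclk", g, w.data, optimize=True)
            L_out = g.shape[2]
            for k in range(K):
                dx[:, :, k : k + L_out] += gp[:, :, :, k]
            x._accumulate(dx)

    return _make(out_data, (x, w, b), backward)


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling (stride == size); trailing remainder dropped."""
    N, C, L = x.data.shape
    L_out = L // size
    trimmed = x.data[:, :, : L_out * size].reshape(N, C, L_out, size)
    arg = trimmed.argmax(axis=3)
    out_data = np.take_along_axis(trimmed, arg[..., None], axis=3)[..., 0]

    def backward(g):
        dt = np.zeros((N, C, L_out, size))
        np.put_along_axis(dt, arg[..., None], g[..., None], axis=3)
        dx = np.zeros_like(x.data)
        dx[:, :, : L_out * size] = dt.reshape(N, C, L_out * size)
        x._accumulate(dx)

    return _make(out_data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return mul(x, Tensor(mask))
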