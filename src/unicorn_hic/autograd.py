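"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the super-resolution network needs:
broadcast arithmetic, ReLU, abs, exp, powers, reductions, channel
concatenation, dense (matrix-vector) products and same-padding 2D
convolution over channel stacks.  Gradients are accumulated by
topological-order backprop; correctness is pinned by finite-difference
tests rather than trusted by construction.

Arrays are small (patches of ~40x40 with <=16 channels), so clarity is
preferred over micro-optimization; convolution is vectorized with
``sliding_window_view`` + ``einsum``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "concat_channels", "dense", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        return Tensor(data, _parents=parents, _backward=backward)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            return (g * e * self.data ** (e - 1),)

        return self._make(self.data ** e, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def abs(self):
        return self._make(np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions / reshaping -------------------------------------------

    def sum(self):
        return self._make(self.data.sum(), (self,),
                          lambda g: (np.broadcast_to(g, self.shape).copy(),))

    def mean(self):
        n = self.data.size
        return self._make(self.data.mean(), (self,),
                          lambda g: (np.broadcast_to(g / n, self.shape).copy(),))

    def mean_spatial(self):
        """(C, H, W) -> (C,) per-channel spatial mean (global pooling)."""
        c, h, w = self.shape
        n = h * w

        def backward(g):
            return (np.broadcast_to(g[:, None, None] / n, self.shape).copy(),)

        return self._make(self.data.mean(axis=(1, 2)), (self,), backward)

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    # -- backprop ----------------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g if parent.grad is not None else g


def relu(x: Tensor) -> Tensor:
    return x.relu()


def concat_channels(parts: list[Tensor]) -> Tensor:
    """Concatenate (C_i, H, W) tensors along the channel axis."""
    sizes = [p.shape[0] for p in parts]
    data = np.concatenate([p.data for p in parts], axis=0)

    def backward(g):
        out, start = [], 0
        for c in sizes:
            out.append(g[start:start + c])
            start += c
        return tuple(out)

    return Tensor(data, _parents=tuple(parts), _backward=backward)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """``w @ x + b`` for vector ``x`` (in,), weights (out, in), bias (out,)."""
    data = w.data @ x.data + b.data

    def backward(g):
        return (w.data.T @ g, np.outer(g, x.data), g)

    return Tensor(data, _parents=(x, w, b), _backward=backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 2D convolution (cross-correlation).

    ``x``: (C_in, H, W); ``w``: (C_out, C_in, k, k) with odd ``k``;
    ``b``: (C_out,).  Output: (C_out, H, W).
    """
    cin, h, wid = x.shape
    cout, cin_w, k, k2 = w.shape
    if cin != cin_w or k != k2 or k % 2 != 1:
        raise ValueError(f"incompatible conv shapes x={x.shape} w={w.shape}")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (Cin, H, W, k, k)
    out = np.einsum("ihwkl,oikl->ohw", win, w.data, optimize=True) + b.data[:, None, None]

    def backward(g):
        # weights: correlate input windows with the output gradient
        dw = np.einsum("ihwkl,ohw->oikl", win, g, optimize=True)
        db = g.sum(axis=(1, 2))
        # input: full correlation of g with the flipped kernel
        gp = np.pad(g, ((0, 0), (pad, pad), (pad, pad)))
        gwin = sliding_window_view(gp, (k, k), axis=(1, 2))  # (Cout, H, W, k, k)
        wf = w.data[:, :, ::-1, ::-1]
        dx = np.einsum("ohwkl,oikl->ihw", gwin, wf, optimize=True)
        return (dx, dw, db)

    return Tensor(out, _parents=(x, w, b), _backward=backward)
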