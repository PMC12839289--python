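"""Compact reverse-mode automatic differentiation over NumPy arrays.

Just the operations the spiking models need: broadcasting arithmetic, matmul,
1-D (grouped) convolution, max-pooling, the usual pointwise nonlinearities,
reductions, shape ops — and the one op that makes surrogate-gradient training
possible: :func:`spike`, whose forward pass is the Heaviside step and whose
backward pass is the fast-sigmoid surrogate slope ``k / (1 + k|u|)^2``.

Gradients flow through a tape built implicitly by the ``parents``/``bwd``
closures on each :class:`Tensor`; ``Tensor.backward()`` topologically sorts
the graph and accumulates into ``.grad``.  Everything is float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf as _erf, expit as _expit

__all__ = ["Tensor", "Parameter", "spike", "concat", "no_grad", "SURROGATE_SLOPE"]

SURROGATE_SLOPE = 25.0

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "parents", "bwd")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        bwd: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self.parents = tuple(parents) if self.requires_grad else ()
        self.bwd = bwd if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node.bwd is not None and node.grad is not None:
                node.bwd(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(
            a.data + b.data,
            a.requires_grad or b.requires_grad,
            (a, b),
            None,
        )
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out.bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out.bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data / b.data, a.requires_grad or b.requires_grad, (a, b))
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
            out.bwd = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))
            out.bwd = bwd
        return out

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g * 0.5 / y)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g * (1 - y**2))
        return out

    def sigmoid(self):
        y = _expit(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g * y * (1 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g * mask)
        return out

    def gelu(self):
        """Exact Gaussian-error-linear unit 0.5 x (1 + erf(x/sqrt(2)))."""
        x = self.data
        cdf = 0.5 * (1 + _erf(x / np.sqrt(2.0)))
        out = Tensor(x * cdf, self.requires_grad, (self,))
        if out.requires_grad:
            pdf = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
            out.bwd = lambda g: self._accum(g * (cdf + x * pdf))
        return out

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if out.requires_grad:
            def bwd(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                    return
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out.bwd = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if out.requires_grad:
            out.bwd = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out.bwd = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out.bwd = bwd
        return out

    # -- structured ops -------------------------------------------------------
    def conv1d(self, w: "Tensor", b: "Tensor | None" = None, stride: int = 1,
               padding: int = 0, groups: int = 1):
        """Grouped 1-D convolution (cross-correlation), x: B x Cin x L."""
        x = self
        B, Cin, L = x.data.shape
        Cout, Cg, K = w.data.shape
        G = groups
        assert Cin == Cg * G and Cout % G == 0
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
        Lout = (xp.shape[2] - K) // stride + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride]
        # cols: B x Cin x Lout x K
        colsg = cols.reshape(B, G, Cg, Lout, K)
        wg = w.data.reshape(G, Cout // G, Cg, K)
        y = np.einsum("bgilk,goik->bgol", colsg, wg, optimize=True).reshape(B, Cout, Lout)
        if b is not None:
            y = y + b.data[None, :, None]
        req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
        parents = (x, w) + ((b,) if b is not None else ())
        out = Tensor(y, req, parents)
        if out.requires_grad:
            def bwd(g):
                gg = g.reshape(B, G, Cout // G, Lout)
                if w.requires_grad:
                    gw = np.einsum("bgol,bgilk->goik", gg, colsg, optimize=True)
                    w._accum(gw.reshape(Cout, Cg, K))
                if b is not None and b.requires_grad:
                    b._accum(g.sum(axis=(0, 2)))
                if x.requires_grad:
                    dcols = np.einsum("bgol,goik->bgilk", gg, wg, optimize=True)
                    dcols = dcols.reshape(B, Cin, Lout, K)
                    dxp = np.zeros_like(xp)
                    for k in range(K):
                        dxp[:, :, k : k + stride * Lout : stride] += dcols[:, :, :, k]
                    x._accum(dxp[:, :, padding : padding + L] if padding else dxp)
            out.bwd = bwd
        return out

    def maxpool1d(self, k: int = 2):
        """Non-overlapping max pooling along the last axis (L divisible by k)."""
        B, C, L = self.data.shape
        assert L % k == 0, "pooling requires length divisible by k"
        xr = self.data.reshape(B, C, L // k, k)
        idx = xr.argmax(axis=3)
        out = Tensor(xr.max(axis=3), self.requires_grad, (self,))
        if out.requires_grad:
            onehot = idx[..., None] == np.arange(k)
            def bwd(g):
                self._accum((g[..., None] * onehot).reshape(B, C, L))
            out.bwd = bwd
        return out


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def spike(u_minus_theta: Tensor, slope: float = SURROGATE_SLOPE) -> Tensor:
    """Heaviside forward (inclusive at 0), fast-sigmoid surrogate backward.

    Forward: 1 where u - theta >= 0.  Backward: d spike / du is approximated
    by ``slope / (1 + slope * |u - theta|)^2`` — symmetric and vanishing for
    large excursions.
    """
    u = u_minus_theta
    y = (u.data >= 0).astype(np.float64)
    out = Tensor(y, u.requires_grad, (u,))
    if out.requires_grad:
        surr = slope / (1 + slope * np.abs(u.data)) ** 2
        out.bwd = lambda g: u._accum(g * surr)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate(datas, axis=axis), req, tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offs = np.cumsum([0] + sizes)
        def bwd(g):
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out.bwd = bwd
    return out
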