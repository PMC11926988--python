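"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`dualsurv.model` is small (token bags of a few dozen
to a few thousand rows, model widths of 16-256), so a plain tape of numpy
operations is fast enough for training on a single CPU.  Two operations
get hand-written backward passes because taping them step by step would
dominate the graph: the selective state-space scan (the per-timestep
recurrence of a Mamba block) and 1-D depthwise convolution expressed via
shifted slices.

Gradients are checked against central finite differences in the test
suite; all arithmetic is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- graph -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad=None):
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        topo, seen = [], set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # ---- elementwise arithmetic -----------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, req, (self, other))
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, req, (self, other))
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, req, (self, other))
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / other.data ** 2)
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, req, (self, other))
        if req:
            a, b = self.data, other.data
            def bwd(g):
                if self.requires_grad:
                    if b.ndim == 1:
                        self._accum(np.outer(g, b) if a.ndim == 2 else g * b)
                    else:
                        self._accum(np.atleast_2d(g) @ b.T if a.ndim == 2
                                    else (g @ b.T))
                if other.requires_grad:
                    if a.ndim == 1:
                        other._accum(np.outer(a, g) if b.ndim == 2 else g * a)
                    else:
                        other._accum(a.T @ np.atleast_2d(g) if b.ndim == 2
                                     else a.T @ g)
            out._backward = bwd
        return out

    # ---- nonlinearities --------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            y = out.data
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / (2.0 * y))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            s = np.sign(self.data)
            out._backward = lambda g: self._accum(g * s)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        if out.requires_grad:
            m = (self.data > 0).astype(np.float64)
            out._backward = lambda g: self._accum(g * m)
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def silu(self):
        s = expit(self.data)
        out = Tensor(self.data * s, self.requires_grad, (self,))
        if out.requires_grad:
            d = s * (1.0 + self.data * (1.0 - s))
            out._backward = lambda g: self._accum(g * d)
        return out

    def softplus(self):
        # numerically stable log(1+e^x)
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            s = expit(self.data)
            out._backward = lambda g: self._accum(g * s)
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        if out.requires_grad:
            m = ((self.data >= lo) & (self.data <= hi)).astype(np.float64)
            out._backward = lambda g: self._accum(g * m)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            def bwd(g):
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))
            out._backward = bwd
        return out

    # ---- reductions and shape ops ---------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bwd(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, shape).astype(np.float64))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, shape).astype(np.float64))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            inv = None if axes is None else np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bwd(g):
                full = np.zeros(shape, dtype=np.float64)
                full[idx] = g
                self._accum(full)
            out._backward = bwd
        return out

    def flip0(self):
        """Reverse along the first (token) axis."""
        out = Tensor(self.data[::-1], self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g[::-1])
        return out

    def pad_rows(self, left: int, right: int):
        """Zero-pad along the first axis."""
        width = [(left, right)] + [(0, 0)] * (self.ndim - 1)
        out = Tensor(np.pad(self.data, width), self.requires_grad, (self,))
        if out.requires_grad:
            n = self.data.shape[0]
            out._backward = lambda g: self._accum(g[left:left + n])
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


def depthwise_conv1d(x: Tensor, taps: Tensor, mode: str = "same") -> Tensor:
    """Per-channel 1-D convolution over the token axis.

    x: (L, C); taps: (C, M).  ``mode='same'`` uses symmetric zero padding
    of (M-1)//2 on each side (M odd); ``mode='causal'`` pads M-1 on the
    left so that output t sees inputs t-M+1..t.
    """
    M = taps.shape[1]
    if mode == "same":
        if M % 2 == 0:
            raise ValueError("same-padded depthwise conv needs an odd width")
        left = right = (M - 1) // 2
    elif mode == "causal":
        left, right = M - 1, 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    L = x.shape[0]
    xp = x.pad_rows(left, right)
    out = None
    for j in range(M):
        term = xp[j:j + L] * taps[:, j]
        out = term if out is None else out + term
    return out


def selective_scan(u: Tensor, delta: Tensor, A: Tensor, B: Tensor,
                   C: Tensor) -> Tensor:
    """Selective (input-dependent) diagonal state-space scan.

    u, delta: (L, D); A: (D, N); B, C: (L, N).  Per timestep the
    continuous pair (A, B_t) is discretized by zero-order hold,
    Ā_t = exp(δ_t A) and B̄_t = (δ_t A)^{-1}(exp(δ_t A) - 1) · δ_t B_t,
    and the recurrence h_t = Ā_t h_{t-1} + B̄_t u_t, y_t = C_t · h_t is
    run from h_0 = 0.  The |δA| → 0 limit B̄ → δ B is taken where
    |δA| < 1e-6.  Backward pass is a hand-written reverse recurrence.
    """
    ud, dd, Ad, Bd, Cd = u.data, delta.data, A.data, B.data, C.data
    L, D = ud.shape
    N = Ad.shape[1]
    if dd.shape != (L, D) or Bd.shape != (L, N) or Cd.shape != (L, N):
        raise ValueError("selective_scan: inconsistent shapes")

    za = dd[:, :, None] * Ad[None]                          # (L, D, N)
    dA = np.exp(za)
    small = np.abs(za) < 1e-6
    safe_A = np.where(np.abs(Ad) < 1e-30, 1.0, Ad)
    F1 = np.where(small, dd[:, :, None], (dA - 1.0) / safe_A[None])  # (L,D,N)
    bu = F1 * Bd[:, None, :]                                # B̄, (L, D, N)

    hs = np.empty((L + 1, D, N))
    hs[0] = 0.0
    drive = bu * ud[:, :, None]
    for t in range(L):
        hs[t + 1] = dA[t] * hs[t] + drive[t]
    y = np.einsum("ldn,ln->ld", hs[1:], Cd)

    req = any(t.requires_grad for t in (u, delta, A, B, C))
    out = Tensor(y, req, (u, delta, A, B, C))
    if req:
        def bwd(gy):
            # adjoint state: GH[t] = Σ_{s>=t} (∂y_s/∂h_t)·gy_s, run backward
            P = gy[:, :, None] * Cd[:, None, :]             # (L, D, N)
            GH = np.empty((L, D, N))
            GH[L - 1] = P[L - 1]
            for t in range(L - 2, -1, -1):
                GH[t] = P[t] + dA[t + 1] * GH[t + 1]
            if C.requires_grad:
                C._accum(np.einsum("ldn,ld->ln", hs[1:], gy))
            if u.requires_grad:
                u._accum(np.einsum("ldn,ldn->ld", GH, bu))
            g_bu = GH * ud[:, :, None]
            if B.requires_grad:
                B._accum(np.einsum("ldn,ldn->ln", g_bu, F1))
            gF1 = g_bu * Bd[:, None, :]
            g_dA = GH * hs[:-1]
            if delta.requires_grad:
                delta._accum((g_dA * dA * Ad[None]).sum(axis=2)
                             + (gF1 * dA).sum(axis=2))
            if A.requires_grad:
                # d F1 / dA, series limit delta^2/2 at small |delta*A|
                dF1_dA = np.where(
                    small, dd[:, :, None] ** 2 / 2.0,
                    (dd[:, :, None] * safe_A[None] * dA - (dA - 1.0))
                    / safe_A[None] ** 2)
                gA = (g_dA * dd[:, :, None] * dA + gF1 * dF1_dA).sum(axis=0)
                A._accum(gA)
        out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
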