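"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for each operation, a
closure that accumulates gradients into its inputs.  ``Tensor.backward()``
runs the closures in reverse topological order.  Only the operations needed
by the conv / GRU / dense models live here: elementwise arithmetic with
broadcasting, matmul, the usual activations, reductions, shape ops, a valid
1-D convolution, max pooling, batch normalisation and the two losses.

Gradients of every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "batchnorm1d",
           "softmax_cross_entropy", "mse_loss", "sigmoid", "tanh", "relu",
           "default_dtype", "DTYPE"]

# float64 by default (exact gradient checks); float32 roughly halves
# training cost and is selected per run via `default_dtype`.
DTYPE = np.float64


@contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype used for newly created tensors."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: closures may hand the same buffer to several parents
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from BPTT exceed recursion depth
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape))
        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, True, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), True, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
            else:
                self._accumulate(np.broadcast_to(
                    np.expand_dims(g, axis), self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), True, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), True, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], True, (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int)) or p is Ellipsis for p in parts)

        def bwd(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:  # basic slices never alias, so in-place add is exact
                self.grad[idx] += g
            else:
                np.add.at(self.grad, idx, g)
        out._backward = bwd
        return out


# -- activations ----------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, True, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))
    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, True, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))
    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, True, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = bwd
    return out


# -- structured primitives -------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution (cross-correlation), stride 1.

    x: (B, C, L); w: (F, C, K); b: (F,).  Output (B, F, L-K+1).
    """
    F, C, K = w.data.shape
    B, _, L = x.data.shape
    Lo = L - K + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)
    # (B, C, Lo, K) -> (B*Lo, C*K) so the contraction runs through BLAS
    win2 = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Lo, C * K)
    w2 = w.data.reshape(F, C * K)
    out_data = (win2 @ w2.T).reshape(B, Lo, F).transpose(0, 2, 1) + b.data[None, :, None]
    out = Tensor(out_data, True, (x, w, b))

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lo, F)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if w.requires_grad:
            w._accumulate((g2.T @ win2).reshape(F, C, K))
        if x.requires_grad:
            # full correlation of g with the flipped kernel
            gp = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)
            gwin2 = np.ascontiguousarray(gwin.transpose(0, 2, 1, 3)).reshape(B * L, F * K)
            wf2 = np.ascontiguousarray(
                w.data[:, :, ::-1].transpose(0, 2, 1)).reshape(F * K, C)
            x._accumulate((gwin2 @ wf2).reshape(B, L, C).transpose(0, 2, 1))
    out._backward = bwd
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (trailing remainder dropped)."""
    B, C, L = x.data.shape
    Lp = L // size
    xv = x.data[:, :, :Lp * size].reshape(B, C, Lp, size)
    arg = xv.argmax(axis=3)
    out = Tensor(xv.max(axis=3), True, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        full = np.zeros_like(x.data)
        b_i, c_i, p_i = np.indices((B, C, Lp))
        full[b_i, c_i, p_i * size + arg] = g
        x._accumulate(full)
    out._backward = bwd
    return out


def batchnorm1d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                train: bool, update_stats: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation for (B, C, L) inputs.

    In training mode batch statistics are used; running statistics are updated
    in place only when `update_stats` is set (they are part of the conv group's
    state, and a frozen group must not drift).
    """
    if train:
        mean = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        if update_stats:
            running_mean *= 1.0 - momentum
            running_mean += momentum * mean
            running_var *= 1.0 - momentum
            running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None]) * inv_std[None, :, None]
    out_data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
    out = Tensor(out_data, True, (x, gamma, beta))
    n = x.data.shape[0] * x.data.shape[2]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = g * gamma.data[None, :, None]
            if train:
                # standard batch-norm backward through batch statistics
                s1 = gx.sum(axis=(0, 2))[None, :, None]
                s2 = (gx * xhat).sum(axis=(0, 2))[None, :, None]
                dx = (gx - s1 / n - xhat * s2 / n) * inv_std[None, :, None]
            else:
                dx = gx * inv_std[None, :, None]
            x._accumulate(dx)
    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under softmax of (B, C) logits."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    B = z.shape[0]
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-300, None)).mean()
    out = Tensor(nll, True, (logits,))

    def bwd(g):
        if logits.requires_grad:
            dp = p.copy()
            dp[np.arange(B), labels] -= 1.0
            logits._accumulate(g * dp / B)
    out._backward = bwd
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()
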