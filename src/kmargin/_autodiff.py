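"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: just the operations the segment classifier and
knowledge head need (dense and 1-D convolutional layers, gated recurrence,
pooling statistics, softmax cross-entropy, mean-squared error).  Gradients are
accumulated by a topological backward sweep; broadcasting is handled by
summing gradients over broadcast axes.  Backward closures receive the output
gradient as an argument and reference only their *inputs*, so graphs are
reference-cycle-free and freed eagerly.  All gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "cross_entropy", "mse", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev")

    def __init__(self, data, prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward = None  # callable(output_grad) or None
        self._prev = tuple(prev)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph machinery -------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
            if node._backward is not None:
                node._backward(node.grad)

    # ---- elementwise -----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        a_shape, b_shape = self.data.shape, other.data.shape

        def _back(g):
            self._accum(_unbroadcast(g, a_shape))
            other._accum(_unbroadcast(g, b_shape))

        out._backward = _back
        return out

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def _back(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _back
        return out

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def sqrt(self, eps: float = 1e-12):
        y = np.sqrt(self.data + eps)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    # ---- shape -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], (self,))
        shape = self.data.shape

        def _back(g):
            full = np.zeros(shape)
            full[idx] = g
            self._accum(full)

        out._backward = _back
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def _back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = _back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along one axis (gradient flows to the first argmax)."""
        am = np.argmax(self.data, axis=axis)
        vals = np.take_along_axis(self.data, np.expand_dims(am, axis), axis)
        out = Tensor(vals.squeeze(axis), (self,))
        shape = self.data.shape

        def _back(g):
            full = np.zeros(shape)
            np.put_along_axis(full, np.expand_dims(am, axis), np.expand_dims(g, axis), axis)
            self._accum(full)

        out._backward = _back
        return out

    # ---- linear algebra --------------------------------------------------
    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, (self, other))

        def _back(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = _back
        return out

    def __matmul__(self, other):
        return self.matmul(other)

    # ---- signal ops ------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Same-padded 1-D convolution (correlation).

        self: (B, Cin, T); weight: (Cout, Cin, k) with k odd; bias: (Cout,).
        """
        x = self.data
        w = weight.data
        b, cin, t = x.shape
        cout, _, k = w.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        xwin = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,Cin,T,k)
        # im2col: one contiguous copy, then BLAS does the heavy lifting
        xcol = np.ascontiguousarray(xwin.transpose(0, 2, 1, 3)).reshape(b * t, cin * k)
        w2 = w.reshape(cout, cin * k)
        y = (xcol @ w2.T).reshape(b, t, cout).transpose(0, 2, 1) + bias.data[None, :, None]
        out = Tensor(y, (self, weight, bias))

        def _back(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(b * t, cout)
            weight._accum((g2.T @ xcol).reshape(cout, cin, k))
            bias._accum(g.sum(axis=(0, 2)))
            dcol = (g2 @ w2).reshape(b, t, cin, k)
            dxp = np.zeros((b, cin, t + 2 * p))
            for j in range(k):  # col2im scatter-add, k is small
                dxp[:, :, j : j + t] += dcol[:, :, :, j].transpose(0, 2, 1)
            self._accum(dxp[:, :, p : p + t])

        out._backward = _back
        return out

    def maxpool1d(self, factor: int):
        """Non-overlapping max pooling along the last axis (right-padded)."""
        x = self.data
        b, c, t = x.shape
        t2 = -(-t // factor) * factor
        xp = np.pad(x, ((0, 0), (0, 0), (0, t2 - t)), constant_values=-np.inf)
        blocks = xp.reshape(b, c, t2 // factor, factor)
        am = np.argmax(blocks, axis=3)
        vals = np.take_along_axis(blocks, am[..., None], axis=3)[..., 0]
        out = Tensor(vals, (self,))

        def _back(g):
            full = np.zeros_like(blocks)
            np.put_along_axis(full, am[..., None], g[..., None], axis=3)
            self._accum(full.reshape(b, c, t2)[:, :, :t])

        out._backward = _back
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    parents = list(tensors)

    def _back(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(parents, pieces):
            t._accum(piece)

    out._backward = _back
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under softmax(logits).

    logits: (B, M); targets: (B,) ints.  Numerically stable log-softmax.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    b = z.shape[0]
    out = Tensor(-logp[np.arange(b), targets].mean(), (logits,))

    def _back(g):
        gz = np.exp(logp)
        gz[np.arange(b), targets] -= 1.0
        logits._accum(g * gz / b)

    out._backward = _back
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error over all elements."""
    diff = pred.data - target
    out = Tensor(np.mean(diff * diff), (pred,))
    out._backward = lambda g: pred._accum(g * 2.0 * diff / diff.size)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain-array softmax over the last axis (no gradient)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
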