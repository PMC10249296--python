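"""A minimal reverse-mode automatic-differentiation engine over NumPy.

Just enough tensor machinery for attention-gated message passing on small
molecular graphs: dense matmul, elementwise arithmetic and nonlinearities,
row gathering, and multiplication by a constant sparse matrix (used for
edge-to-node aggregation and node-to-graph pooling).  Everything runs in
float64 on CPU; gradients are accumulated by topological-order backward
passes.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            self.requires_grad and self._accumulate(g)
            other.requires_grad and other._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            self.requires_grad and self._accumulate(g * other.data)
            other.requires_grad and other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            self.requires_grad and self._accumulate(g / other.data)
            other.requires_grad and other._accumulate(
                -g * self.data / (other.data**2)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)

        def backward(g):
            self.requires_grad and self._accumulate(g @ other.data.T)
            other.requires_grad and other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + exp(x)), computed stably for large |x|
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accumulate(g * sig)

        return self._make(out_data, (self,), backward)

    # -- reductions and reshaping -----------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accumulate(np.asarray(g).reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]``; backward scatters gradients with np.add.at."""
    index = np.asarray(index, dtype=np.int64)

    def backward(g):
        grad = np.zeros_like(t.data)
        np.add.at(grad, index, g)
        t._accumulate(grad)

    return t._make(t.data[index], (t,), backward)


def spmm(matrix: sparse.spmatrix, t: Tensor) -> Tensor:
    """Multiply a constant sparse matrix by a tensor: ``matrix @ t``."""
    mat = matrix.tocsr()

    def backward(g):
        t._accumulate(mat.T @ g)

    return t._make(mat @ t.data, (t,), backward)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a column vector within each segment.

    The per-segment max is subtracted as a constant for numerical
    stability, which leaves the gradient unchanged.
    """
    seg = np.asarray(segment_ids, dtype=np.int64)
    flat = scores.data.reshape(-1)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, seg, flat)
    shifted = scores - Tensor(seg_max[seg].reshape(scores.shape))
    e = shifted.exp()
    pool = sparse.csr_matrix(
        (np.ones(len(seg)), (seg, np.arange(len(seg)))), shape=(num_segments, len(seg))
    )
    denom = spmm(pool, e.reshape(-1, 1))  # (num_segments, 1)
    return e / gather(denom, seg).reshape(*scores.shape)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
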