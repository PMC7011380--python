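"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based autodiff core sized for this package's networks: dense
layers, 1-D convolutions, gated recurrences, batch normalization and the two
output heads all build computation graphs of :class:`Tensor` nodes, and
``Tensor.backward()`` accumulates gradients by reverse topological sweep.
Arrays are float64 throughout, which keeps gradient checks tight and runs
deterministically on one CPU.

Only the primitives the network needs are provided; each op records a
closure that maps the output gradient to parent gradients.  Broadcasting in
``+``/``*`` is supported and un-broadcast on the way back.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "embedding_lookup",
    "conv1d_same",
    "softmax_cross_entropy",
    "softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: an ndarray plus gradient plumbing."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # ------------------------------------------------------------------ ops

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward=backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __matmul__ = matmul

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape: int) -> "Tensor":
        old_shape = self.data.shape

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def slice_axis1(self, start: int, stop: int) -> "Tensor":
        """Static slice along the last-but-usable axis 1 of a 2-D tensor."""
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accumulate(full)

        return Tensor(self.data[:, start:stop], parents=(self,), backward=backward)

    # ------------------------------------------------------------- backward

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; accumulates into ``.grad``."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs include per-timestep recurrence nodes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def embedding_lookup(weights: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of a (vocab, d) weight matrix by an integer index array."""
    indices = np.asarray(indices, dtype=np.int64)
    out_data = weights.data[indices]

    def backward(g: np.ndarray) -> None:
        if weights.requires_grad:
            grad = np.zeros_like(weights.data)
            np.add.at(grad, indices.reshape(-1), g.reshape(-1, weights.data.shape[1]))
            weights._accumulate(grad)

    return Tensor(out_data, parents=(weights,), backward=backward)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution with stride 1 and same padding.

    ``x`` is (batch, length, c_in); ``w`` is (kernel, c_in, c_out);
    ``b`` is (c_out,).  Output is (batch, length, c_out).
    """
    batch, length, c_in = x.data.shape
    kernel, _, c_out = w.data.shape
    pad_left = (kernel - 1) // 2
    pad_right = kernel - 1 - pad_left
    xp = np.pad(x.data, ((0, 0), (pad_left, pad_right), (0, 0)))
    # cols: (batch, length, kernel, c_in) via explicit taps (kernel is tiny)
    cols = np.stack([xp[:, k:k + length, :] for k in range(kernel)], axis=2)
    cols2 = cols.reshape(batch * length, kernel * c_in)
    w2 = w.data.reshape(kernel * c_in, c_out)
    out_data = (cols2 @ w2).reshape(batch, length, c_out) + b.data

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(batch * length, c_out)
        if w.requires_grad:
            w._accumulate((cols2.T @ g2).reshape(kernel, c_in, c_out))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w2.T).reshape(batch, length, kernel, c_in)
            dxp = np.zeros_like(xp)
            for k in range(kernel):
                dxp[:, k:k + length, :] += dcols[:, :, k, :]
            x._accumulate(dxp[:, pad_left:pad_left + length, :])

    return Tensor(out_data, parents=(x, w, b), backward=backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain (n, k) array (numerically shifted)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (n, k) logits against integer class labels."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean()

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(float(g) * grad / n)

    return Tensor(loss, parents=(logits,), backward=backward)


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Tensor], learning_rate: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.learning_rate = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[:] = b1 * m + (1 - b1) * p.grad
            v[:] = b2 * v + (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= self.learning_rate * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
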