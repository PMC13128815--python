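"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the trainable models: a small tape-based
autodiff engine in the micrograd style, but array-valued, with exactly the
operations the pipeline needs (affine maps, gating nonlinearities, softmax,
same-length 1-D convolution) plus an Adam optimizer.  Everything is float64
and deterministic; there is no device abstraction and no broadcasting magic
beyond what the ops below declare.

Gradient correctness is pinned by finite-difference tests rather than by
construction, so keep each op's backward close to its textbook form.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "stack",
    "softmax",
    "conv1d_same",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient tape node.

    Only tensors reachable from a parameter (``requires_grad=True``) carry
    graph edges; constants stay leaf nodes with no parents, so forward passes
    over frozen inputs do not grow the tape.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return Tensor._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a.grad += -g

        return Tensor._node(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return Tensor._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul is implemented for 2-D operands only")

        def backward(g):
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += a.data.T @ g

        return Tensor._node(a.data @ b.data, (a, b), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return Tensor._node(a.data[idx], (a,), backward)

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def backward(g):
            if a.requires_grad:
                a.grad += g.reshape(orig)

        return Tensor._node(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a.grad += g.transpose(inv)

        return Tensor._node(a.data.transpose(axes), (a,), backward)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a.grad += np.broadcast_to(g, a.data.shape)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a.grad += np.broadcast_to(gg, a.data.shape)

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self):
        a = self
        n = a.data.size

        def backward(g):
            if a.requires_grad:
                a.grad += np.broadcast_to(g / n, a.data.shape)

        return Tensor._node(a.data.mean(), (a,), backward)

    # -- nonlinearities --------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a.grad += g * mask

        return Tensor._node(np.where(mask, a.data, 0.0), (a,), backward)

    def sigmoid(self):
        a = self
        # numerically stable logistic
        out_data = np.empty_like(a.data)
        pos = a.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
        ez = np.exp(a.data[~pos])
        out_data[~pos] = ez / (1.0 + ez)

        def backward(g):
            if a.requires_grad:
                a.grad += g * out_data * (1.0 - out_data)

        return Tensor._node(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a.grad += g * (1.0 - out_data * out_data)

        return Tensor._node(out_data, (a,), backward)

    # -- autodiff driver -------------------------------------------------

    def backward(self):
        """Accumulate gradients of `self` (summed to a scalar) into leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def build(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            if t.grad is None or t._parents:
                t.grad = np.zeros_like(t.data)
        # leaves keep previously accumulated grads only if zero_grad was not
        # called; interior nodes always start fresh.
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad = self.grad + np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors of identical shape along a new axis."""
    parts = [Tensor._lift(t) for t in tensors]

    def backward(g):
        pieces = np.split(g, len(parts), axis=axis)
        for p, piece in zip(parts, pieces):
            if p.requires_grad:
                p.grad += np.squeeze(piece, axis=axis)

    return Tensor._node(np.stack([p.data for p in parts], axis=axis), parts, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along `axis`, computed with max-subtraction for stability."""
    a = Tensor._lift(x)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a.grad += out_data * (g - dot)

    return Tensor._node(out_data, (a,), backward)


def conv1d_same(x: Tensor, kernels: Tensor, biases: Tensor) -> Tensor:
    """Same-length 1-D convolution (cross-correlation) with zero padding.

    Shapes: x (batch, length, c_in), kernels (c_out, c_in, k) with odd k,
    biases (c_out,) -> output (batch, length, c_out).
    """
    x = Tensor._lift(x)
    kernels = Tensor._lift(kernels)
    biases = Tensor._lift(biases)
    batch, length, c_in = x.data.shape
    c_out, c_in_k, k = kernels.data.shape
    if c_in_k != c_in:
        raise ValueError(f"kernel expects {c_in_k} input channels, got {c_in}")
    if k % 2 == 0:
        raise ValueError("kernel length must be odd for symmetric padding")
    pad = k // 2
    xp = np.zeros((batch, length + 2 * pad, c_in))
    xp[:, pad : pad + length, :] = x.data

    out_data = np.broadcast_to(biases.data, (batch, length, c_out)).copy()
    for j in range(k):
        out_data += xp[:, j : j + length, :] @ kernels.data[:, :, j].T

    def backward(g):
        if biases.requires_grad:
            biases.grad += g.sum(axis=(0, 1))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for j in range(k):
            window = xp[:, j : j + length, :]
            if kernels.requires_grad:
                kernels.grad[:, :, j] += np.einsum("blo,blc->oc", g, window)
            if gxp is not None:
                gxp[:, j : j + length, :] += g @ kernels.data[:, :, j]
        if x.requires_grad:
            x.grad += gxp[:, pad : pad + length, :]

    return Tensor._node(out_data, (x, kernels, biases), backward)


class Adam:
    """Adam optimizer with standard bias correction (Kingma & Ba defaults)."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
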