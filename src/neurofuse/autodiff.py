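"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the models in this package need: broadcasted
elementwise arithmetic, matrix products, reductions, leaky-ReLU, stable
(log-)softmax, concatenation, reshaping and row gathering.  Gradients are
accumulated on a tape built eagerly during the forward pass and replayed in
reverse topological order by :meth:`Tensor.backward`.

All data is float64.  The engine is deliberately small and CPU-only; every
backward rule is exercised by a central-finite-difference check in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "clip_global_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum along axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---------------------------------------------------------------- helpers
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # `own` promises the caller created `grad` fresh (no aliasing), so it
        # may be adopted without a defensive copy
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = _unbroadcast(g, a.shape)
                a._accum(ga, own=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.shape)
                b._accum(gb, own=gb is not g)

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g, own=True)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape), own=True)
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape), own=True)

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape), own=True)
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape), own=True)

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T, own=True)
            if b.requires_grad:
                b._accum(a.data.T @ g, own=True)

        return self._node(self.data @ other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0), own=True)

        return self._node(self.data**e, (self,), backward)

    # -------------------------------------------------------------- unary ops
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, d=out_data):
            if a.requires_grad:
                a._accum(g * d, own=True)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data, own=True)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, d=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / d, own=True)

        return self._node(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g, a=self, f=factor):
            if a.requires_grad:
                a._accum(g * f, own=True)

        return self._node(self.data * factor, (self,), backward)

    def relu(self):
        return self.leaky_relu(slope=0.0)

    @property
    def T(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.T)

        return self._node(self.data.T, (self,), backward)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g, a=self, s=orig):
            if a.requires_grad:
                a._accum(g.reshape(s))

        return self._node(self.data.reshape(*shape), (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        orig = self.shape

        def backward(g, a=self, ax=axis, kd=keepdims, s=orig):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, s))

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # --------------------------------------------------------------- indexing
    def take_rows(self, index: np.ndarray):
        """Gather rows (axis 0) by an integer index array."""
        idx = np.asarray(index)

        def backward(g, a=self, i=idx):
            if a.requires_grad:
                buf = np.zeros_like(a.data)
                np.add.at(buf, i, g)
                a._accum(buf, own=True)

        return self._node(self.data[idx], (self,), backward)

    # ----------------------------------------------------- softmax and friends
    def log_softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        lse = m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))
        out_data = x - lse
        soft = np.exp(out_data)

        def backward(g, a=self, s=soft, ax=axis):
            if a.requires_grad:
                a._accum(g - s * g.sum(axis=ax, keepdims=True), own=True)

        return self._node(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        x = self.data
        e = np.exp(x - x.max(axis=axis, keepdims=True))
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, sm=s, ax=axis):
            if a.requires_grad:
                a._accum(sm * (g - (g * sm).sum(axis=ax, keepdims=True)), own=True)

        return self._node(s, (self,), backward)

    # ---------------------------------------------------------------- backward
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient on backward."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, off=offsets, ax=axis):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer over a fixed list of parameters (default moments)."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}
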