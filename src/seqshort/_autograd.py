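"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the model needs: broadcast-aware
arithmetic, matmul, row softmax, layer normalization, GELU, reductions,
reshaping and concatenation.  Gradients are accumulated in float64 or
float32 according to the data dtype; graphs are built eagerly and freed
after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "layer_norm", "gelu", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph bookkeeping ---------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the graph as we go; leaf grads survive
                node._backward = None
                node._parents = ()

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward, req)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward, req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward, req)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward, req)

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward, self.requires_grad)

    # -- reductions & shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward, self.requires_grad
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward, self.requires_grad)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward, self.requires_grad)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward, req
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (row max subtracted before exponentiation)."""
    x = Tensor._coerce(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            x._accum(p * (g - dot))

    return Tensor._make(p, (x,), backward, x.requires_grad)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._coerce(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    p = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accum(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable scale/shift."""
    x = Tensor._coerce(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    n = x.data.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            # standard layer-norm backward
            dx = (
                gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(dx)

    return Tensor._make(out_data, (x, gamma, beta), backward, req)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """GELU, tanh approximation."""
    x = Tensor._coerce(x)
    u = _GELU_C * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    out_data = 0.5 * x.data * (1.0 + t)

    def backward(g):
        if x.requires_grad:
            du = _GELU_C * (1.0 + 3 * 0.044715 * x.data**2)
            dx = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t**2) * du
            x._accum(g * dx)

    return Tensor._make(out_data, (x,), backward, x.requires_grad)
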