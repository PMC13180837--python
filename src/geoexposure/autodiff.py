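"""Minimal reverse-mode automatic differentiation over numpy arrays.

The exposure-response network needs gradients with respect to both its
parameters (training) and its inputs (attribution, vulnerability mapping,
monotonicity checks).  The model is small and fully dense at desk scale, so
a compact tape-based engine over :class:`numpy.ndarray` is sufficient and
keeps the dependency surface to numpy alone.  Only the primitives the
pipeline composes are provided: broadcast arithmetic, (batched) matrix
multiplication, elementwise nonlinearities, reductions, indexing and axis
manipulation.  Softmax and layer normalization are built by composition, so
their gradients come for free.

All data is float64; gradients are accumulated, so a tensor used twice
receives the sum of both contributions (the chain rule for shared nodes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "relu", "sigmoid", "tanh", "exp", "sqrt", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this tensor.

        `grad` seeds the output gradient (defaults to 1 for scalars).
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------ shape / indexing
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, idx, g)

        return Tensor(out_data, _parents=(self,), _backward=bw)


def tensor(x) -> Tensor:
    """Wrap `x` as a constant Tensor (no-op on existing Tensors)."""
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------ nonlinearities
def relu(x: Tensor) -> Tensor:
    x = tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def exp(x: Tensor) -> Tensor:
    x = tensor(x)
    out_data = np.exp(x.data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * out_data)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    x = tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, _parents=(x,), _backward=bw)


def tanh(x: Tensor) -> Tensor:
    x = tensor(x)
    out_data = np.tanh(x.data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data**2))

    return Tensor(out_data, _parents=(x,), _backward=bw)


def sqrt(x: Tensor) -> Tensor:
    return tensor(x) ** 0.5


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (composed from primitives).

    The max shift is treated as a constant, which is exact: softmax is
    invariant to additive shifts along the reduced axis.
    """
    x = tensor(x)
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Standardize over the last axis (no learnable affine)."""
    x = tensor(x)
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / sqrt(var + eps)


def pad_axis(x: Tensor, axis: int, left: int, right: int = 0) -> Tensor:
    """Zero-pad `x` along one axis (used for causal convolution shifts)."""
    x = tensor(x)
    if left == 0 and right == 0:
        return x
    spec = [(0, 0)] * x.ndim
    spec[axis] = (left, right)
    out_data = np.pad(x.data, spec)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(left, out_data.shape[axis] - right or None)
    sl = tuple(sl)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[sl])

    return Tensor(out_data, _parents=(x,), _backward=bw)


# ------------------------------------------------------------------ training
class Adam:
    """Full-batch Adam over a dict of parameter Tensors.

    Scale-adaptive per coordinate, so the sum-scale objective used by the
    weighted training loss needs no manual normalization.
    """

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**self._t)
            vhat = self._v[k] / (1 - b2**self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
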