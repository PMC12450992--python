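"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  The op set is deliberately small — exactly what a
windowed-attention / convolutional classifier needs — and every primitive is
covered by finite-difference gradient checks in the test suite.

Conventions
-----------
* Feature maps are ``(B, C, H, W)``; token stacks are ``(N, T, C)``.
* Gradients are plain ``ndarray``s stored on ``Tensor.grad``; non-leaf
  tensors keep their gradient only when ``retain_grad()`` was called
  (used by the Grad-CAM implementation).
* A module-level switch (:func:`no_grad`) disables taping for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_backward", "_parents",
                 "_retain", "_accumulate")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype != np.float32 else np.float32)
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._retain = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"],
            backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._retain = False
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out.requires_grad = False
            out._parents = ()
            out._backward = None
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def retain_grad(self) -> "Tensor":
        self._retain = True
        return self

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None or node._retain:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                node._accumulate = grads  # type: ignore[attr-defined]
                node._backward(g)
                del node._accumulate  # type: ignore[attr-defined]

    def _send(self, parent: "Tensor", grad: np.ndarray) -> None:
        """Route a gradient contribution to ``parent`` during backward."""
        if not parent.requires_grad:
            return
        acc: dict[int, np.ndarray] = self._accumulate  # type: ignore[attr-defined]
        key = id(parent)
        if key in acc:
            acc[key] = acc[key] + grad
        else:
            acc[key] = grad

    # -- elementwise arithmetic ----------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            out._send(a, _unbroadcast(g, a.shape))
            out._send(b, _unbroadcast(g, b.shape))

        out = Tensor._op(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            out._send(a, -g)

        out = Tensor._op(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            out._send(a, _unbroadcast(g * b.data, a.shape))
            out._send(b, _unbroadcast(g * a.data, b.shape))

        out = Tensor._op(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            out._send(a, _unbroadcast(g / b.data, a.shape))
            out._send(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        out = Tensor._op(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g, a=self, p=exponent):
            out._send(a, g * p * a.data ** (p - 1))

        out = Tensor._op(out_data, (self,), backward)
        return out

    # -- transcendental -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self):
            out._send(a, g * out.data)

        out = Tensor._op(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward(g, a=self):
            out._send(a, g / a.data)

        out = Tensor._op(out_data, (self,), backward)
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g, a=self, m=mask):
            out._send(a, g * m)

        out = Tensor._op(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self):
            out._send(a, g * out.data * (1.0 - out.data))

        out = Tensor._op(out_data, (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is None:
                grad = np.broadcast_to(g, a.shape)
            else:
                if not kd:
                    axes = (ax,) if isinstance(ax, int) else tuple(ax)
                    axes = tuple(x % a.ndim for x in axes)
                    g = np.expand_dims(g, tuple(sorted(axes)))
                grad = np.broadcast_to(g, a.shape)
            out._send(a, grad.astype(a.data.dtype, copy=False))

        out = Tensor._op(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g, a=self):
            out._send(a, g.reshape(a.shape))

        out = Tensor._op(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g, a=self, inv=tuple(inv)):
            out._send(a, g.transpose(inv))

        out = Tensor._op(out_data, (self,), backward)
        return out

    def swap_last(self):
        """Transpose the last two axes (for attention score computation)."""
        axes = tuple(range(self.ndim - 2)) + (self.ndim - 1, self.ndim - 2)
        return self.transpose(axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx, g)
            out._send(a, grad)

        out = Tensor._op(out_data, (self,), backward)
        return out

    # -- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if b.ndim >= 2:
                bt = np.swapaxes(b.data, -1, -2)
            else:
                bt = b.data[:, None]
            if a.ndim >= 2:
                at = np.swapaxes(a.data, -1, -2)
            else:
                at = a.data[None, :]
            ga = g @ bt if a.ndim >= 2 or g.ndim >= 2 else g * bt
            gb = at @ g
            out._send(a, _unbroadcast(np.asarray(ga), a.shape))
            out._send(b, _unbroadcast(np.asarray(gb), b.shape))

        out = Tensor._op(out_data, (self, other), backward)
        return out


# -- free functions -----------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out._send(t, g[tuple(sl)])

    out = Tensor._op(out_data, tensors, backward)
    return out


def pad2d(x: Tensor, pads: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the last two axes: pads = (top, bottom, left, right)."""
    t, b, l, r = pads
    spec = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    out_data = np.pad(x.data, spec)

    def backward(g):
        sl = [slice(None)] * (x.ndim - 2) + [
            slice(t, g.shape[-2] - b if b else None),
            slice(l, g.shape[-1] - r if r else None),
        ]
        out._send(x, g[tuple(sl)])

    out = Tensor._op(out_data, (x,), backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding.

    Forward uses a strided sliding-window view plus einsum; the input
    gradient is assembled by kernel-offset slices, which are disjoint for
    stride ≥ 1 and therefore safe for ``+=``.
    """
    B, C, H, W = x.shape
    O, Ci, kh, kw = weight.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {Ci}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    out_data = np.einsum("bchwij,ocij->bohw", view, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        gw = np.einsum("bchwij,bohw->ocij", view, g, optimize=True)
        out._send(weight, gw)
        if bias is not None:
            out._send(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            gcol = np.einsum("bohw,ocij->bchwij", g, weight.data, optimize=True)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += gcol[:, :, :, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:Hp - padding, padding:Wp - padding]
            out._send(x, gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._op(out_data, parents, backward)
    return out


def take_rows(x: Tensor, rows: np.ndarray) -> Tensor:
    """Select rows along axis 0 by integer index (rows need not be unique)."""
    rows = np.asarray(rows, dtype=np.intp)
    out_data = x.data[rows]

    def backward(g):
        grad = np.zeros_like(x.data)
        np.add.at(grad, rows, g)
        out._send(x, grad)

    out = Tensor._op(out_data, (x,), backward)
    return out


def scatter_rows(x: Tensor, rows: np.ndarray, total: int) -> Tensor:
    """Inverse of :func:`take_rows` for unique ``rows``: place ``x[i]`` at
    ``rows[i]`` in a zero tensor with ``total`` rows."""
    rows = np.asarray(rows, dtype=np.intp)
    out_shape = (total,) + x.shape[1:]
    out_data = np.zeros(out_shape, dtype=x.data.dtype)
    out_data[rows] = x.data

    def backward(g):
        out._send(x, g[rows])

    out = Tensor._op(out_data, (x,), backward)
    return out
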