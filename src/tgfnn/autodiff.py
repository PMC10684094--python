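"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The fuzzy network has well under a thousand parameters, so a small
tape-based engine operating on dense float64 arrays is both fast enough
and exact enough for gradient-based training.  Every public math helper
in this module dispatches on its argument type: plain ``numpy`` arrays
(or scalars) take the fast eager path, :class:`Tensor` arguments build a
computation graph.  Library code can therefore be written once and run
either eagerly (inference, interpretation) or differentiably (training).

Only the operations the network needs are implemented: elementwise
arithmetic, ``exp``/``log``, stable ``softplus``/``sigmoid``,
``logsumexp``, reductions, clipping, binary ``einsum``, ``concatenate``
and ``reshape``.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "asarray",
    "exp",
    "log",
    "softplus",
    "sigmoid",
    "logsumexp",
    "clip",
    "asum",
    "amean",
    "einsum2",
    "concatenate",
    "reshape",
    "cumsum",
    "take",
    "grad",
]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` over axes that were broadcast from ``shape``."""
    if g.shape == shape:
        return g
    # leading axes added by broadcasting
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_vjp")

    # keep NumPy from absorbing Tensors into object arrays; binary ops
    # then fall back to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._vjp = vjp  # callable(out_grad) -> tuple of parent grads

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor({self.data!r})"

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, other):
        return power(self, other)

    def sum(self, axis=None, keepdims=False):
        return asum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    # -- backward pass ---------------------------------------------------
    def backward(self, seed: np.ndarray | float = 1.0):
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.broadcast_to(np.asarray(seed, dtype=np.float64), self.shape).copy()
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            parent_grads = node._vjp(node.grad)
            for p, g in zip(node._parents, parent_grads):
                if g is None:
                    continue
                g = _unbroadcast(np.asarray(g, dtype=np.float64), p.data.shape)
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def _val(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def asarray(x):
    """Underlying ndarray of a Tensor, or ``np.asarray`` of anything else."""
    return _val(x)


# -- primitive ops -------------------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return _val(a) + _val(b)
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.data + b.data, (a, b), lambda g: (g, g))


def sub(a, b):
    if not _is_tensor(a, b):
        return _val(a) - _val(b)
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.data - b.data, (a, b), lambda g: (g, -g))


def mul(a, b):
    if not _is_tensor(a, b):
        return _val(a) * _val(b)
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.data * b.data, (a, b), lambda g: (g * b.data, g * a.data))


def div(a, b):
    if not _is_tensor(a, b):
        return _val(a) / _val(b)
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data / b.data,
        (a, b),
        lambda g: (g / b.data, -g * a.data / (b.data * b.data)),
    )


def power(a, b):
    """``a ** b`` for positive base ``a`` (general tensor exponent)."""
    if not _is_tensor(a, b):
        return _val(a) ** _val(b)
    a, b = _wrap(a), _wrap(b)
    out = a.data ** b.data

    def vjp(g):
        ga = g * b.data * a.data ** (b.data - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            gb = g * out * np.log(a.data)
        return ga, gb

    return Tensor(out, (a, b), vjp)


def exp(a):
    if not _is_tensor(a):
        return np.exp(_val(a))
    a = _wrap(a)
    out = np.exp(a.data)
    return Tensor(out, (a,), lambda g: (g * out,))


def log(a):
    if not _is_tensor(a):
        return np.log(_val(a))
    a = _wrap(a)
    return Tensor(np.log(a.data), (a,), lambda g: (g / a.data,))


def sigmoid(a):
    x = _val(a)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if not _is_tensor(a):
        return out
    return Tensor(out, (a,), lambda g: (g * out * (1.0 - out),))


def softplus(a):
    """log(1 + exp(x)), overflow-safe via the log-sum-exp identity."""
    x = _val(a)
    out = np.logaddexp(0.0, x)
    if not _is_tensor(a):
        return out
    return Tensor(out, (a,), lambda g: (g * sigmoid(x),))


def logsumexp(a, axis=None, keepdims=False):
    x = _val(a)
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.sum(np.exp(x - m), axis=axis, keepdims=True)
    out = m + np.log(s)
    if not keepdims:
        out_r = np.squeeze(out, axis=axis) if axis is not None else out.reshape(())
    else:
        out_r = out
    if not _is_tensor(a):
        return out_r

    def vjp(g):
        gk = g if keepdims else (
            np.expand_dims(g, axis=axis) if axis is not None else np.reshape(g, out.shape)
        )
        return (gk * np.exp(x - out),)

    return Tensor(out_r, (a,), vjp)


def clip(a, lo, hi):
    """Clamp to [lo, hi]; gradient is identity inside, zero outside."""
    x = _val(a)
    out = np.clip(x, lo, hi)
    if not _is_tensor(a):
        return out
    mask = ((x >= lo) if lo is not None else True) & ((x <= hi) if hi is not None else True)
    return Tensor(out, (a,), lambda g: (g * mask,))


def asum(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return np.sum(_val(a), axis=axis, keepdims=keepdims)
    a = _wrap(a)
    out = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape),)
        gk = g if keepdims else np.expand_dims(g, axis=axis)
        return (np.broadcast_to(gk, a.data.shape),)

    return Tensor(out, (a,), vjp)


def amean(a, axis=None, keepdims=False):
    n = _val(a).size if axis is None else _val(a).shape[axis]
    return div(asum(a, axis=axis, keepdims=keepdims), float(n))


def einsum2(subscripts: str, a, b):
    """Binary einsum; each operand's indices must appear in the other or the output."""
    if not _is_tensor(a, b):
        return np.einsum(subscripts, _val(a), _val(b))
    a, b = _wrap(a), _wrap(b)
    ins, sout = subscripts.replace(" ", "").split("->")
    sa, sb = ins.split(",")
    out = np.einsum(subscripts, a.data, b.data)

    def vjp(g):
        ga = np.einsum(f"{sout},{sb}->{sa}", g, b.data)
        gb = np.einsum(f"{sout},{sa}->{sb}", g, a.data)
        return ga, gb

    return Tensor(out, (a, b), vjp)


def concatenate(arrays, axis=0):
    if not _is_tensor(*arrays):
        return np.concatenate([_val(x) for x in arrays], axis=axis)
    arrays = [_wrap(x) for x in arrays]
    out = np.concatenate([x.data for x in arrays], axis=axis)
    sizes = [x.data.shape[axis] for x in arrays]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(arrays), vjp)


def reshape(a, shape):
    if not _is_tensor(a):
        return np.reshape(_val(a), shape)
    a = _wrap(a)
    return Tensor(np.reshape(a.data, shape), (a,), lambda g: (g.reshape(a.data.shape),))


def cumsum(a, axis=-1):
    if not _is_tensor(a):
        return np.cumsum(_val(a), axis=axis)
    a = _wrap(a)
    out = np.cumsum(a.data, axis=axis)

    def vjp(g):
        return (np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis),)

    return Tensor(out, (a,), vjp)


def take(a, idx, axis=0):
    """Index along one axis (integer array or slice semantics via np.take)."""
    if not _is_tensor(a):
        return np.take(_val(a), idx, axis=axis)
    a = _wrap(a)
    axis = axis % a.data.ndim
    out = np.take(a.data, idx, axis=axis)

    def vjp(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, tuple([slice(None)] * axis + [idx]), g)
        return (ga,)

    return Tensor(out, (a,), vjp)


def grad(loss: Tensor, params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    """Backpropagate a scalar loss and collect gradients for named leaves."""
    if loss.data.shape != ():
        raise ValueError("grad expects a scalar loss")
    loss.backward()
    return {
        k: (p.grad if p.grad is not None else np.zeros_like(p.data))
        for k, p in params.items()
    }
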