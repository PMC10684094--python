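"""Differentiable fuzzy-logic primitives with tropical-geometry smoothing.

A continuous clinical measurement is encoded into three graded concepts
("low", "medium", "high") by smoothed trapezoidal membership functions
built from differences of a scaled softplus

    f_eps(x) = eps * log(1 + exp(x / eps)),

which converges to the hinge max(0, x) as eps -> 0.  Conjunction and
disjunction of membership degrees use a parameterized T-norm / T-conorm
family: the T-norm interpolates between the product (eps2 -> 1) and the
minimum (eps2 -> 0); the T-conorm between addition (eps3 -> 1) and the
maximum (eps3 -> 0).  The eps -> 0 regime is the tropical (min/max) limit
in which the network degenerates to crisp rule logic.

All functions accept NumPy arrays or :mod:`tgfnn.autodiff` tensors and
broadcast like NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad

__all__ = [
    "MembershipParams",
    "SmoothnessState",
    "smoothed_hinge",
    "membership",
    "tnorm",
    "tconorm",
    "anneal_eps",
]

CONCEPTS = ("low", "medium", "high")

#: floor applied to T-norm inputs so that x^(negative exponent) stays finite
TNORM_INPUT_FLOOR = 1e-6


@dataclass
class MembershipParams:
    """Cutoffs and smoothness of the trapezoidal membership functions.

    Parameters
    ----------
    cutoffs : ndarray, shape (n_features, 4)
        Per continuous feature, ordered cutoffs ``a1 <= a2 <= a3 <= a4``
        in standardized feature units.  The "low" concept plateaus below
        ``a1`` and vanishes above ``a2``; "high" mirrors this on
        ``[a3, a4]``; "medium" is the complementary trapezoid.  Strict
        inequality is required for ``a1 < a2`` and ``a3 < a4`` since the
        ramp slopes divide by those gaps.
    eps1 : float
        Smoothness of the membership ramps, in (0, 1).
    """

    cutoffs: np.ndarray
    eps1: float = 0.5

    def __post_init__(self):
        self.cutoffs = np.atleast_2d(np.asarray(self.cutoffs, dtype=np.float64))
        if self.cutoffs.shape[-1] != 4:
            raise ValueError("cutoffs must have 4 columns (a1..a4)")
        if not (0.0 < self.eps1 < 1.0):
            raise ValueError(f"eps1 must lie in (0, 1), got {self.eps1}")
        a = self.cutoffs
        if np.any(np.diff(a, axis=-1) < 0):
            raise ValueError("cutoffs must be non-decreasing per feature")
        if np.any(a[..., 1] <= a[..., 0]) or np.any(a[..., 3] <= a[..., 2]):
            raise ValueError("need a1 < a2 and a3 < a4 (ramp gaps must be positive)")


@dataclass
class SmoothnessState:
    """Shared smoothness eps with its geometric annealing schedule.

    One eps drives the membership functions, T-norm and T-conorm.  It
    starts at 0.99 and decays by a factor ``gamma`` at every optimizer
    step, floored at ``eps_min``; it is scheduled, not trained.
    """

    eps: float = 0.99
    eps_min: float = 0.01
    gamma: float = 0.999
    step: int = 0

    def __post_init__(self):
        if not (0.0 < self.eps_min <= self.eps <= 0.99):
            raise ValueError("require 0 < eps_min <= eps <= 0.99")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.step < 0:
            raise ValueError("step must be non-negative")


def anneal_eps(state: SmoothnessState) -> SmoothnessState:
    """One annealing step: ``eps <- max(eps_min, eps * gamma)``.

    Applied once per optimizer step; cumulatively the schedule equals
    ``max(eps_min, 0.99 * gamma**step)``.
    """
    return replace(state, eps=max(state.eps_min, state.eps * state.gamma), step=state.step + 1)


def smoothed_hinge(x, eps):
    """``f_eps(x) = eps * log(1 + exp(x / eps))`` — a smoothed max(0, x).

    Monotone increasing in ``x``; converges to the hinge as ``eps -> 0``.
    Evaluated through the log-sum-exp identity so large ``x / eps`` does
    not overflow.
    """
    if np.any(ad.asarray(eps) <= 0):
        raise ValueError("eps must be positive")
    return eps * ad.softplus(x / eps)


def _validate_membership_inputs(x, a):
    xv = ad.asarray(x)
    if not np.all(np.isfinite(xv)):
        raise ValueError("membership input contains non-finite values")
    av = ad.asarray(a)
    if np.any(np.diff(av, axis=-1) < 0) or np.any(av[..., 1] <= av[..., 0]) or np.any(
        av[..., 3] <= av[..., 2]
    ):
        raise ValueError("invalid cutoff ordering")


def membership(x, cutoffs, eps1, concept: str | None = None, *, validate: bool = True):
    """Degree to which ``x`` belongs to a fuzzy concept of its feature.

    The three concepts are smoothed trapezoids built from the scaled
    softplus ``f = smoothed_hinge(., eps1)`` with gap-normalized
    arguments::

        l(x) = f((a2 - x)/(a2 - a1)) - f((a1 - x)/(a2 - a1))
        m(x) = f((x - a1)/(a2 - a1)) - f((x - a2)/(a2 - a1))
             - f((a3 - x)/(a4 - a3)) + f((a4 - x)/(a4 - a3)) - 1
        h(x) = f((x - a3)/(a4 - a3)) - f((x - a4)/(a4 - a3))

    As ``eps1 -> 0`` these converge to the crisp trapezoids: "low" is 1
    below ``a1`` and ramps to 0 at ``a2``; "high" ramps from 0 at ``a3``
    to 1 at ``a4``; "medium" is 1 on ``[a2, a3]`` and 0 outside
    ``[a1, a4]``.  Values may overshoot [0, 1] by O(eps1); they are not
    clipped here (clamping happens at the T-norm input).

    Parameters
    ----------
    x : array-like or Tensor
        Standardized measurement(s).
    cutoffs : array-like or Tensor, shape (..., 4)
        Ordered cutoffs ``(a1, a2, a3, a4)``, broadcastable against ``x``.
    eps1 : float
        Smoothness in (0, 1).
    concept : {"low", "medium", "high"} or None
        Which membership to evaluate; ``None`` returns all three stacked
        on a new trailing axis.
    """
    if validate and not isinstance(x, ad.Tensor) and not isinstance(cutoffs, ad.Tensor):
        _validate_membership_inputs(x, cutoffs)

    def f(z):
        return smoothed_hinge(z, eps1)

    is_t = isinstance(cutoffs, ad.Tensor)
    a1 = ad.take(cutoffs, 0, axis=-1) if is_t else ad.asarray(cutoffs)[..., 0]
    a2 = ad.take(cutoffs, 1, axis=-1) if is_t else ad.asarray(cutoffs)[..., 1]
    a3 = ad.take(cutoffs, 2, axis=-1) if is_t else ad.asarray(cutoffs)[..., 2]
    a4 = ad.take(cutoffs, 3, axis=-1) if is_t else ad.asarray(cutoffs)[..., 3]
    g12 = a2 - a1
    g34 = a4 - a3

    def low():
        return f((a2 - x) / g12) - f((a1 - x) / g12)

    def high():
        return f((x - a3) / g34) - f((x - a4) / g34)

    def medium():
        return (
            f((x - a1) / g12) - f((x - a2) / g12)
            - f((a3 - x) / g34) + f((a4 - x) / g34) - 1.0
        )

    if concept is None:
        parts = [low(), medium(), high()]
        if any(isinstance(p, ad.Tensor) for p in parts):
            parts = [ad.reshape(p, p.shape + (1,)) for p in parts]
            return ad.concatenate(parts, axis=-1)
        return np.stack(parts, axis=-1)
    try:
        return {"low": low, "medium": medium, "high": high}[concept]()
    except KeyError:
        raise ValueError(f"unknown concept {concept!r}") from None


def tnorm(values, exponents=None, eps2=0.5, *, axis=-1, clamp=True):
    """Parameterized N-input T-norm (fuzzy AND) with importance exponents.

    Computes::

        T(x; M) = ( sum_i x_i^(M_i * (eps2-1)/eps2) - N + 1 )^(eps2/(eps2-1))

    where each input is weighted by exponentiation with its connection
    weight ``M_i`` in [0, 1] (``M_i = 0`` removes the input; ``M_i = 1``
    uses it fully).  The family interpolates between the product
    (``eps2 -> 1``) and the minimum (``eps2 -> 0``).

    Inputs are clamped to ``[TNORM_INPUT_FLOOR, 1]`` before
    exponentiation; the inner exponent is then non-positive, every term
    is >= 1 and the inner base is >= 1, so the whole computation is done
    in log space (logsumexp) and cannot overflow even for eps2 near 0.
    With ``clamp=False`` the raw formula is evaluated and a negative
    inner base raises a domain error.
    """
    if not (0.0 < eps2 < 1.0):
        raise ValueError(f"eps2 must lie in (0, 1), got {eps2}")
    shp = ad.asarray(values).shape
    n = shp[axis] if shp else 1
    if exponents is None:
        exponents = np.ones(n)
    c = (eps2 - 1.0) / eps2  # < 0
    if not clamp:
        v = ad.asarray(values)
        base = np.sum(v ** (ad.asarray(exponents) * c), axis=axis) - n + 1.0
        if np.any(base < 0):
            raise FloatingPointError("T-norm inner base is negative with clamping disabled")
        return base ** (1.0 / c)
    x = ad.clip(values, TNORM_INPUT_FLOOR, 1.0)
    li = ad.mul(exponents * c, ad.log(x))  # each term >= 0
    lse = ad.logsumexp(li, axis=axis)  # log sum x^(Mc) >= log N
    log_base = lse + ad.log(1.0 - (n - 1.0) * ad.exp(-lse))
    return ad.exp(log_base / c)


def tconorm(values, eps3=0.5, *, axis=-1):
    """Parameterized K-input T-conorm (fuzzy OR).

    Computes ``(sum_k v_k^(1/eps3))^eps3`` for non-negative inputs,
    interpolating between addition (``eps3 -> 1``) and the maximum
    (``eps3 -> 0``).  Permutation invariant and monotone in every input;
    a single input is returned unchanged for any eps3.  Evaluated in log
    space so small inputs raised to 1/eps3 do not underflow to zero.
    """
    if not (0.0 < eps3 < 1.0):
        raise ValueError(f"eps3 must lie in (0, 1), got {eps3}")
    v = ad.asarray(values)
    if not np.all(np.isfinite(v)):
        raise ValueError("tconorm inputs must be finite")
    if not isinstance(values, ad.Tensor):
        if np.any(v < 0):
            raise ValueError("tconorm inputs must be non-negative")
        if v.shape and v.shape[axis] == 1:
            return np.squeeze(v, axis=axis)  # exact identity on one input
        with np.errstate(divide="ignore"):  # zeros map to -inf and drop out
            return np.exp(eps3 * _np_logsumexp(np.log(v) / eps3, axis=axis))
    x = ad.clip(values, 1e-300, None)
    return ad.exp(eps3 * ad.logsumexp(ad.log(x) / eps3, axis=axis))


def _np_logsumexp(x, axis):
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m, axis=axis) + np.log(np.sum(np.exp(x - m), axis=axis))
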