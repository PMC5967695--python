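"""Bijections between constrained and unconstrained parameter scales.

Samplers in this package operate exclusively on an unconstrained space.
Parameters declared with bounds are mapped through one of four bijections
(identity, log for one-sided bounds, logit for intervals), and the
log-Jacobian of the inverse map is added to the target density so the
posterior on the constrained scale is preserved.

The two-sided map is the logistic bijection.  This is a deliberate dialect
choice: it is monotone, infinitely differentiable, and has a simple
log-Jacobian; no bit-compatibility with any other system's interval
transform is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundKind",
    "unconstrain",
    "constrain",
    "log_jacobian",
    "make_bounded_model",
]

# relative clamp applied when a constrained value sits numerically on a bound
_CLAMP = 1e-12


@dataclass(frozen=True)
class BoundKind:
    """Classification of a parameter's support.

    ``lower``/``upper`` may be ``-inf``/``+inf``; the four cases
    (unbounded, lower-only, upper-only, two-sided) select the bijection.
    """

    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got ({self.lower}, {self.upper})")

    @property
    def kind(self) -> str:
        lo = math.isfinite(self.lower)
        hi = math.isfinite(self.upper)
        if lo and hi:
            return "two-sided"
        if lo:
            return "lower-only"
        if hi:
            return "upper-only"
        return "unbounded"


def _sigmoid(y: float) -> float:
    # numerically stable logistic
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    e = math.exp(y)
    return e / (1.0 + e)


def _softplus(t: float) -> float:
    return max(t, 0.0) + math.log1p(math.exp(-abs(t)))


def unconstrain(x: float, b: BoundKind) -> float:
    """Map a constrained value ``x`` strictly inside ``(lower, upper)`` to R."""
    k = b.kind
    if k == "unbounded":
        return float(x)
    if k == "lower-only":
        if x <= b.lower:
            raise ValueError(f"value {x} not above lower bound {b.lower}")
        return math.log(x - b.lower)
    if k == "upper-only":
        if x >= b.upper:
            raise ValueError(f"value {x} not below upper bound {b.upper}")
        return math.log(b.upper - x)
    # two-sided: logit of the rescaled position
    if not (b.lower < x < b.upper):
        raise ValueError(f"value {x} outside open interval ({b.lower}, {b.upper})")
    z = (x - b.lower) / (b.upper - b.lower)
    return math.log(z) - math.log1p(-z)


def constrain(y: float, b: BoundKind) -> float:
    """Inverse of :func:`unconstrain`; maps any finite real inside the bounds.

    Results numerically at a bound are nudged into the open interval by a
    relative 1e-12 so round trips never land on ±infinity.
    """
    k = b.kind
    if k == "unbounded":
        return float(y)
    if k == "lower-only":
        return b.lower + math.exp(y)
    if k == "upper-only":
        return b.upper - math.exp(y)
    width = b.upper - b.lower
    x = b.lower + width * _sigmoid(y)
    eps = _CLAMP * width
    return min(max(x, b.lower + eps), b.upper - eps)


def log_jacobian(y: float, b: BoundKind) -> tuple[float, float]:
    """Return ``(log|dx/dy|, d log|dx/dy| / dy)`` at unconstrained ``y``."""
    k = b.kind
    if k == "unbounded":
        return 0.0, 0.0
    if k in ("lower-only", "upper-only"):
        # x = lower + e^y  (or upper - e^y): |dx/dy| = e^y
        return float(y), 1.0
    s = _sigmoid(y)
    # log sigma(y) + log(1 - sigma(y)) = -softplus(-y) - softplus(y),
    # stable for |y| large where sigma saturates
    logj = math.log(b.upper - b.lower) - _softplus(-y) - _softplus(y)
    return logj, 1.0 - 2.0 * s


def make_bounded_model(specs, logp_grad_constrained, name: str = "bounded"):
    """Wrap a constrained-scale log density as an unconstrained ModelPosterior.

    ``logp_grad_constrained(x) -> (logp, grad)`` is evaluated on the
    constrained scale; bounds from ``specs`` are applied internally and the
    Jacobian adjustment (plus its gradient) added, so users write densities
    on the natural scale — mirroring how bound vectors are passed to a
    sampler front-end and handled transparently.
    """
    from .model_api import ModelPosterior  # local import to avoid a cycle

    bounds = [BoundKind(s.lower, s.upper) for s in specs]

    class _Bounded(ModelPosterior):
        def logp_grad(self, q):
            q = np.asarray(q, dtype=float)
            x = np.array([constrain(qi, b) for qi, b in zip(q, bounds)])
            lp, gx = logp_grad_constrained(x)
            gx = np.asarray(gx, dtype=float)
            gq = np.empty_like(gx)
            for i, (yi, b) in enumerate(zip(q, bounds)):
                lj, dlj = log_jacobian(yi, b)
                lp += lj
                # dx/dy = exp(log|dx/dy|) with the sign of the map
                dxdy = math.exp(lj)
                if b.kind == "upper-only":
                    dxdy = -dxdy
                gq[i] = gx[i] * dxdy + dlj
            return lp, gq

    return _Bounded(specs, name=name)
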