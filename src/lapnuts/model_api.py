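"""Model contract shared by the samplers, plus mode finding and post-hoc tools.

A model is anything exposing an unconstrained log-posterior density and its
gradient together with per-parameter metadata (:class:`ParameterSpec`).  All
Jacobian terms for internal transforms belong inside the density: the
samplers are geometry-agnostic.

Gradients are analytic and hand-coded per model; central finite differences
serve only as a verification oracle (:func:`check_gradient`), never as the
sampling path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .transforms import BoundKind, constrain

__all__ = [
    "ParameterSpec",
    "ModelPosterior",
    "FunctionModel",
    "ModeResult",
    "check_gradient",
    "find_mode",
    "fd_hessian",
    "mceval",
]


@dataclass(frozen=True)
class ParameterSpec:
    """Metadata for one scalar parameter.

    ``role`` distinguishes parameters sampled by the outer sampler
    ("fixed") from those designated for marginalization ("random").
    ``init`` is on the constrained scale and must lie strictly inside
    ``(lower, upper)``.
    """

    name: str
    lower: float = -math.inf
    upper: float = math.inf
    role: str = "fixed"
    init: float = 0.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: require lower < upper")
        if not self.lower < self.init < self.upper:
            raise ValueError(f"{self.name}: init {self.init} not inside bounds")
        if self.role not in ("fixed", "random"):
            raise ValueError(f"{self.name}: role must be 'fixed' or 'random'")

    @property
    def bound(self) -> BoundKind:
        return BoundKind(self.lower, self.upper)


class ModelPosterior:
    """Base class for models: unconstrained log-density, gradient, metadata.

    Subclasses implement :meth:`logp_grad`.  Optionally they may implement
    ``uu_hessian(q, random_index)`` returning the negative-Hessian block of
    the random-effect coordinates (used by the Laplace machinery; finite
    differences are the fallback).
    """

    def __init__(self, specs: Sequence[ParameterSpec], name: str = "model"):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        self.specs = specs
        self.name = name

    @property
    def dim(self) -> int:
        return len(self.specs)

    @property
    def param_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def init_point(self) -> np.ndarray:
        from .transforms import unconstrain

        return np.array([unconstrain(s.init, s.bound) for s in self.specs])

    def random_index(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specs) if s.role == "random"], dtype=int)

    def fixed_index(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specs) if s.role == "fixed"], dtype=int)

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(q)[0]

    def constrain(self, q: np.ndarray) -> np.ndarray:
        """Map an unconstrained draw to the constrained (reporting) scale."""
        return np.array([constrain(qi, s.bound) for qi, s in zip(q, self.specs)])


class FunctionModel(ModelPosterior):
    """Model defined by a plain ``logp_grad`` callable."""

    def __init__(self, specs, logp_grad_fn: Callable, name: str = "model"):
        super().__init__(specs, name=name)
        self._fn = logp_grad_fn

    def logp_grad(self, q):
        return self._fn(np.asarray(q, dtype=float))


def check_gradient(model: ModelPosterior, q: np.ndarray, step: float = 1e-5) -> float:
    """Maximum relative error of the analytic gradient vs central differences.

    Relative error per coordinate is |analytic - fd| / (|fd| + 1e-12).
    Raises if the density is non-finite at any stencil point.
    """
    q = np.asarray(q, dtype=float)
    lp, grad = model.logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("log density not finite at q")
    worst = 0.0
    for i in range(model.dim):
        qp = q.copy()
        qm = q.copy()
        qp[i] += step
        qm[i] -= step
        lp_p = model.logp(qp)
        lp_m = model.logp(qm)
        if not (np.isfinite(lp_p) and np.isfinite(lp_m)):
            raise ValueError(f"non-finite density perturbing coordinate {i} ({model.param_names[i]})")
        fd = (lp_p - lp_m) / (2.0 * step)
        worst = max(worst, abs(grad[i] - fd) / (abs(fd) + 1e-12))
    return worst


@dataclass
class ModeResult:
    """Posterior mode with curvature.

    ``hessian`` is the negative second derivative of the log density at the
    mode; ``covariance`` its inverse (the usual asymptotic covariance, e.g.
    for a dense mass matrix or a mode-based Metropolis proposal).
    """

    mode: np.ndarray
    hessian: np.ndarray | None
    covariance: np.ndarray | None
    converged: bool
    grad_norm: float = math.nan
    n_iter: int = 0


def fd_hessian(grad_fn: Callable[[np.ndarray], np.ndarray], q: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function from its gradient.

    Per-coordinate step ``step * max(1, |q_i|)``; result symmetrized.
    """
    q = np.asarray(q, dtype=float)
    d = q.size
    H = np.empty((d, d))
    for i in range(d):
        h = step * max(1.0, abs(q[i]))
        qp = q.copy()
        qm = q.copy()
        qp[i] += h
        qm[i] -= h
        H[i] = (grad_fn(qp) - grad_fn(qm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def find_mode(
    model: ModelPosterior,
    q0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ModeResult:
    """Quasi-Newton ascent of the log density with a curvature estimate.

    BFGS climbs until the gradient norm falls below ``tol``; the Hessian of
    the negative log density is then formed by central differences of the
    analytic gradient and inverted for the covariance.  Non-convergence
    yields ``converged=False`` and no covariance.
    """
    if q0 is None:
        q0 = model.init_point()
    q0 = np.asarray(q0, dtype=float)
    if not np.isfinite(model.logp(q0)):
        raise ValueError("log density not finite at starting point")

    def negobj(q):
        lp, g = model.logp_grad(q)
        if not np.isfinite(lp):
            return 1e100, np.zeros_like(q)
        return -lp, -g

    res = optimize.minimize(
        negobj, q0, jac=True, method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    _, g = model.logp_grad(res.x)
    gnorm = float(np.linalg.norm(g))
    converged = gnorm < max(tol, 1e-5)
    if not converged:
        return ModeResult(res.x, None, None, False, gnorm, res.nit)
    H = fd_hessian(lambda q: -model.logp_grad(q)[1], res.x)
    try:
        np.linalg.cholesky(H)
        cov = np.linalg.inv(H)
        cov = 0.5 * (cov + cov.T)
    except np.linalg.LinAlgError:
        return ModeResult(res.x, H, None, False, gnorm, res.nit)
    return ModeResult(res.x, H, cov, True, gnorm, res.nit)


def mceval(fn: Callable, fit, include_warmup: bool = False) -> pd.DataFrame:
    """Evaluate a derived quantity on every saved post-warmup draw.

    ``fn`` maps a constrained draw vector to a scalar, a sequence, or a
    mapping of named quantities; the result table has one row per
    post-warmup draw across merged chains.  Failures name the offending
    draw index.
    """
    draws = fit.draws_constrained(include_warmup=include_warmup)
    rows = []
    for idx, draw in enumerate(draws):
        try:
            out = fn(draw)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"mceval function failed on draw {idx}: {exc}") from exc
        if isinstance(out, dict):
            rows.append(out)
        elif np.isscalar(out):
            rows.append({"value": out})
        else:
            rows.append({f"v{i}": v for i, v in enumerate(np.atleast_1d(out))})
    return pd.DataFrame(rows)
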