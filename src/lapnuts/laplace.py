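"""Laplace-marginalized posteriors: NUTS over fixed effects only.

Designated random effects are integrated out of the joint density with a
Laplace approximation recomputed at every density evaluation — i.e. at
each step of each NUTS trajectory — so the outer sampler is unaware the
random effects exist.  The inner problem (the conditional mode of the
random effects given the fixed effects) is solved by a damped Newton
ascent; the marginal density is

    logp(theta) = logp(theta, u_hat) + (n_u/2) log(2 pi) - (1/2) logdet H

with H the negative Hessian of the joint density in u at u_hat.  The outer
gradient is formed by central finite differences of the marginal density
(a documented, model-agnostic substitute for implicit differentiation),
with the inner solve warm-started from the previous mode.

If the Laplace approximation is accurate, the posterior of the fixed
effects is the same whether the random effects are integrated by Laplace
or sampled in full — which is exactly what the audit in
``diagnostics.compare_versions`` checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model_api import ModelPosterior

__all__ = ["LaplaceConfig", "LaplaceResult", "inner_mode", "laplace_marginal",
           "LaplaceMarginalModel", "make_marginal_model"]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LaplaceConfig:
    """Settings for the inner optimization and outer finite differences."""

    random_index: np.ndarray | None = None  # defaults to the model's declared random role
    inner_tol: float = 1e-8
    inner_max_iter: int = 100
    fd_step: float = 1e-5
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.inner_tol <= 0:
            raise ValueError("inner_tol must be positive")


@dataclass
class LaplaceResult:
    """Outcome of one inner Laplace solve."""

    u_hat: np.ndarray
    hessian: np.ndarray
    logdet_H: float
    marginal_logp: float
    inner_iters: int
    converged: bool


def _complement(dim: int, ridx: np.ndarray) -> np.ndarray:
    mask = np.ones(dim, dtype=bool)
    mask[ridx] = False
    return np.nonzero(mask)[0]


class _InnerSolver:
    """Newton ascent over the random-effect block at fixed theta.

    Holds the preallocated joint parameter vector and the (fixed, random)
    index split; one instance is reused across evaluations so warm starts
    and index bookkeeping cost nothing per call.
    """

    def __init__(self, joint: ModelPosterior, ridx: np.ndarray, cfg: LaplaceConfig):
        self.joint = joint
        self.ridx = np.asarray(ridx, dtype=int)
        self.fidx = _complement(joint.dim, self.ridx)
        self.cfg = cfg
        self.q = np.empty(joint.dim)
        self._analytic_hess = hasattr(joint, "uu_hessian")

    def _logp_grad_u(self, theta, u):
        self.q[self.fidx] = theta
        self.q[self.ridx] = u
        lp, g = self.joint.logp_grad(self.q)
        return lp, g[self.ridx]

    def _neg_hess_u(self, theta, u):
        self.q[self.fidx] = theta
        self.q[self.ridx] = u
        if self._analytic_hess:
            return np.asarray(self.joint.uu_hessian(self.q, self.ridx), dtype=float)
        from .model_api import fd_hessian

        def gu(uv):
            qq = self.q.copy()
            qq[self.ridx] = uv
            return -self.joint.logp_grad(qq)[1][self.ridx]

        return fd_hessian(gu, u, step=self.cfg.fd_step)

    def solve(self, theta: np.ndarray, u0: np.ndarray):
        """Return (u_hat, H, chol(H), lp_joint, converged, iters)."""
        cfg = self.cfg
        u = np.array(u0, dtype=float)
        lp, gu = self._logp_grad_u(theta, u)
        if not math.isfinite(lp):
            return u, None, None, lp, False, 0
        it = 0
        for it in range(1, cfg.inner_max_iter + 1):
            if float(np.abs(gu).max()) < cfg.inner_tol:
                break
            H = self._neg_hess_u(theta, u)
            try:
                L = np.linalg.cholesky(H)
                step = np.linalg.solve(L.T, np.linalg.solve(L, gu))
            except np.linalg.LinAlgError:
                step = gu / max(1.0, float(np.linalg.norm(gu)))
            alpha = 1.0
            for _ in range(20):
                u_new = u + alpha * step
                lp_new, gu_new = self._logp_grad_u(theta, u_new)
                if math.isfinite(lp_new) and lp_new >= lp - 1e-12:
                    break
                alpha *= 0.5
            else:
                return u, self._neg_hess_u(theta, u), None, lp, False, it
            u, lp, gu = u_new, lp_new, gu_new
        H = self._neg_hess_u(theta, u)
        converged = bool(np.abs(gu).max() < cfg.inner_tol)
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return u, H, None, lp, False, it
        return u, H, L, lp, converged, it

    def marginal(self, theta: np.ndarray, u0: np.ndarray):
        """Laplace marginal log density and the solved mode, or (-inf, u0)."""
        u_hat, H, L, lp, converged, _ = self.solve(theta, u0)
        if not converged or L is None:
            _warn_once("inner Laplace optimization failed to converge; density set to -inf")
            return -math.inf, u_hat
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        return lp + 0.5 * self.ridx.size * _LOG_2PI - 0.5 * logdet, u_hat


def _warn_once(msg: str) -> None:
    # first occurrence at WARNING, repeats at DEBUG: failures recur
    # benignly at extreme theta during step-size search and divergences
    level = logging.DEBUG if getattr(_warn_once, "_seen", False) else logging.WARNING
    _warn_once._seen = True
    logger.log(level, msg)


def inner_mode(
    joint: ModelPosterior,
    theta: np.ndarray,
    u0: np.ndarray,
    cfg: LaplaceConfig,
    random_index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Newton ascent of the joint density in u at fixed theta.

    Returns (u_hat, H, converged, iterations) with H the negative Hessian
    block in u at u_hat (analytic when the model provides ``uu_hessian``,
    central differences of the gradient otherwise).  Steps that fail to
    increase the density are halved; a non-SPD terminal Hessian reports
    non-convergence.
    """
    ridx = np.asarray(random_index if random_index is not None else joint.random_index())
    solver = _InnerSolver(joint, ridx, cfg)
    u_hat, H, L, _, converged, it = solver.solve(np.asarray(theta, float), u0)
    if H is None:
        H = np.eye(u_hat.size)
    return u_hat, H, converged, it


def laplace_marginal(
    joint: ModelPosterior,
    theta: np.ndarray,
    cfg: LaplaceConfig,
    state: dict | None = None,
) -> float:
    """Laplace approximation of log ∫ exp logp(theta, u) du.

    ``state`` (optional mutable dict) carries the warm-start mode between
    calls.  Inner non-convergence yields -inf (the outer transition is then
    treated as divergent).
    """
    ridx = np.asarray(cfg.random_index if cfg.random_index is not None else joint.random_index())
    solver = _InnerSolver(joint, ridx, cfg)
    if state is not None and cfg.warm_start and "u" in state:
        u0 = state["u"]
    else:
        u0 = np.zeros(ridx.size)
    lp, u_hat = solver.marginal(np.asarray(theta, float), u0)
    if state is not None and math.isfinite(lp):
        state["u"] = u_hat
    return lp


class LaplaceMarginalModel(ModelPosterior):
    """A ModelPosterior over the fixed effects embedding the inner Laplace solve.

    The gradient is central finite differences of the marginal density with
    per-coordinate step ``fd_step * max(1, |theta_i|)``; every evaluation
    warm-starts the inner Newton from the previous conditional mode (cold
    starts begin at zero, the non-centered scale's prior mean).
    """

    def __init__(self, joint: ModelPosterior, cfg: LaplaceConfig | None = None):
        cfg = cfg or LaplaceConfig()
        ridx = np.asarray(cfg.random_index if cfg.random_index is not None
                          else joint.random_index())
        if ridx.size == 0:
            raise ValueError("no random-effect coordinates to marginalize")
        fidx = _complement(joint.dim, ridx)
        if fidx.size == 0:
            raise ValueError("no fixed-effect coordinates left to sample")
        specs = [joint.specs[i] for i in fidx]
        super().__init__(specs, name=f"{joint.name}_laplace")
        self.joint = joint
        self.cfg = LaplaceConfig(random_index=ridx, inner_tol=cfg.inner_tol,
                                 inner_max_iter=cfg.inner_max_iter,
                                 fd_step=cfg.fd_step, warm_start=cfg.warm_start)
        self._solver = _InnerSolver(joint, ridx, self.cfg)
        self._u_warm = np.zeros(ridx.size)

    def __deepcopy__(self, memo):
        # fresh solver and warm-start buffer; the joint model is shared
        # read-only, so chains remain independent
        new = LaplaceMarginalModel(self.joint, self.cfg)
        memo[id(self)] = new
        return new

    def _u0(self) -> np.ndarray:
        return self._u_warm if self.cfg.warm_start else np.zeros(self._u_warm.size)

    def marginal_logp(self, theta: np.ndarray) -> float:
        lp, u_hat = self._solver.marginal(np.asarray(theta, float), self._u0())
        if self.cfg.warm_start and math.isfinite(lp):
            self._u_warm = u_hat
        return lp

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        lp = self.marginal_logp(theta)
        if not math.isfinite(lp):
            return -math.inf, np.zeros(theta.size)
        g = np.empty(theta.size)
        for i in range(theta.size):
            h = self.cfg.fd_step * max(1.0, abs(theta[i]))
            tp = theta.copy()
            tm = theta.copy()
            tp[i] += h
            tm[i] -= h
            lp_p, _ = self._solver.marginal(tp, self._u0())
            lp_m, _ = self._solver.marginal(tm, self._u0())
            if not (math.isfinite(lp_p) and math.isfinite(lp_m)):
                return -math.inf, np.zeros(theta.size)
            g[i] = (lp_p - lp_m) / (2.0 * h)
        return lp, g


def make_marginal_model(joint: ModelPosterior, cfg: LaplaceConfig | None = None) -> LaplaceMarginalModel:
    """Build the marginal model over fixed effects (the 'laplace' toggle)."""
    return LaplaceMarginalModel(joint, cfg)
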