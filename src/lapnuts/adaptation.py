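"""Warmup self-tuning: step size, adaptation schedule, mass matrix.

The procedure mirrors the Stan warmup design: a fast initial buffer where
only the step size adapts, a sequence of doubling "slow" windows during
which draws are accumulated and the (diagonal or dense) inverse mass matrix
is re-estimated at each window end, and a terminal buffer that re-settles
the step size under the final metric.  Step-size adaptation is
Nesterov-style dual averaging toward a target acceptance statistic, with
the conventional constants gamma=0.05, t0=10, kappa=0.75 and
mu = log(10 * eps0); dual averaging restarts at every metric update.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .metric import Metric
from .model_api import ModelPosterior
from .nuts_core import PhasePoint, hamiltonian, leapfrog

__all__ = [
    "DualAveragingState",
    "AdaptationSchedule",
    "Metric",
    "da_init",
    "da_update",
    "build_schedule",
    "estimate_metric",
    "find_reasonable_stepsize",
    "WarmupAdapter",
]

logger = logging.getLogger(__name__)

# shrinkage weight n0 and scale of the identity regularizer for metric
# estimation (Stan-style: cov <- n/(n+n0) * sample + n0/(n+n0) * tau * I)
_REG_N0 = 5.0
_REG_TAU = 1e-3


@dataclass
class DualAveragingState:
    """State of the dual-averaging recursion for log step size."""

    mu: float
    log_eps: float
    log_eps_bar: float = 0.0
    H_bar: float = 0.0
    t: int = 0
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    delta: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("target acceptance delta must be in (0, 1)")


def da_init(eps0: float, delta: float = 0.8) -> DualAveragingState:
    """Fresh dual-averaging state anchored at mu = log(10 * eps0)."""
    return DualAveragingState(mu=math.log(10.0 * eps0), log_eps=math.log(eps0), delta=delta)


def da_update(s: DualAveragingState, accept: float) -> DualAveragingState:
    """One dual-averaging step given the latest acceptance statistic."""
    accept = min(max(float(accept), 0.0), 1.0)
    t = s.t + 1
    w = 1.0 / (t + s.t0)
    H_bar = (1.0 - w) * s.H_bar + w * (s.delta - accept)
    log_eps = s.mu - math.sqrt(t) / s.gamma * H_bar
    eta = t ** (-s.kappa)
    log_eps_bar = eta * log_eps + (1.0 - eta) * s.log_eps_bar
    return replace(s, t=t, H_bar=H_bar, log_eps=log_eps, log_eps_bar=log_eps_bar)


@dataclass
class AdaptationSchedule:
    """Warmup phase layout: buffers and doubling metric windows."""

    warmup: int
    init_buffer: int
    term_buffer: int
    base_window: int
    window_ends: list[int] = field(default_factory=list)


def build_schedule(
    warmup: int,
    init_buffer: int = 75,
    term_buffer: int = 50,
    base_window: int = 25,
) -> AdaptationSchedule:
    """Stan-style warmup windowing.

    Windows tile [init_buffer, warmup - term_buffer); each doubles the
    previous, and a window that could not be followed by a full double is
    extended to absorb the remainder.  Short warmups degrade gracefully to
    proportionally shrunken buffers around a single window.
    """
    if warmup <= 0:
        raise ValueError("warmup must be positive")
    if warmup < init_buffer + term_buffer + base_window:
        # scale the phases down proportionally, keeping a single window
        total = init_buffer + term_buffer + base_window
        init_buffer = int(round(0.15 * warmup))
        term_buffer = int(round(0.10 * warmup))
        base_window = warmup - init_buffer - term_buffer
        if base_window <= 0:
            init_buffer = term_buffer = 0
            base_window = warmup
        return AdaptationSchedule(warmup, init_buffer, term_buffer, base_window,
                                  window_ends=[warmup - term_buffer])

    ends: list[int] = []
    pos = init_buffer
    size = base_window
    last = warmup - term_buffer
    while pos < last:
        next_size = 2 * size
        if pos + size + next_size > last:
            # cannot fit the doubled successor: extend this window to the end
            ends.append(last)
            break
        ends.append(pos + size)
        pos += size
        size = next_size
    return AdaptationSchedule(warmup, init_buffer, term_buffer, base_window, window_ends=ends)


def estimate_metric(window_draws: np.ndarray, kind: str = "diag", prev: Metric | None = None) -> Metric:
    """Regularized variance/covariance of warmup draws as the inverse mass.

    Shrinks toward a small identity:  (n/(n+5)) * sample + (5/(n+5)) * 1e-3 * I.
    With fewer than 5 draws the previous metric is kept (a warning is
    logged); ``prev`` is required in that case.
    """
    X = np.atleast_2d(np.asarray(window_draws, dtype=float))
    n = X.shape[0]
    if n < 5:
        logger.warning("metric window has %d < 5 draws; keeping previous metric", n)
        if prev is None:
            raise ValueError("fewer than 5 draws and no previous metric to keep")
        return prev
    w = n / (n + _REG_N0)
    if kind == "diag":
        var = X.var(axis=0, ddof=1)
        return Metric.diag(w * var + (1.0 - w) * _REG_TAU)
    if kind == "dense":
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = w * cov + (1.0 - w) * _REG_TAU * np.eye(X.shape[1])
        return Metric.dense(cov)
    raise ValueError(f"cannot estimate metric of kind {kind!r}")


def find_reasonable_stepsize(
    model: ModelPosterior,
    q0: np.ndarray,
    metric: Metric,
    rng: np.random.Generator,
    eps_init: float = 1.0,
) -> float:
    """Coarse initial step size by doubling/halving until the one-step
    acceptance probability crosses 1/2."""
    q0 = np.asarray(q0, dtype=float)
    pt = PhasePoint.at(q0, metric.sample_momentum(rng), model)
    if not math.isfinite(pt.logp):
        raise ValueError("non-finite log density at the step-size search point")
    H0 = hamiltonian(pt, metric)
    eps = float(eps_init)

    def log_ratio(e: float) -> float:
        H1 = hamiltonian(leapfrog(pt, e, metric, model), metric)
        return H0 - H1  # log of the one-step acceptance ratio

    a = 1.0 if log_ratio(eps) > math.log(0.5) else -1.0
    while a * log_ratio(eps) > -a * math.log(2.0):
        eps *= 2.0 ** a
        if not 1e-10 < eps < 1e10:
            raise RuntimeError("step-size search left [1e-10, 1e10]; check the model scale")
    return eps


class WarmupAdapter:
    """Drives step-size and metric adaptation across a warmup phase.

    One instance per chain.  ``metric_kind`` in {"unit", "diag", "dense"};
    a user-supplied dense metric (e.g. a mode-based covariance) bypasses
    metric adaptation entirely, and a user-supplied step size bypasses dual
    averaging.
    """

    def __init__(
        self,
        model: ModelPosterior,
        warmup: int,
        metric_kind: str = "diag",
        delta: float = 0.8,
        fixed_metric: Metric | None = None,
        fixed_stepsize: float | None = None,
        init_buffer: int = 75,
        term_buffer: int = 50,
        base_window: int = 25,
    ):
        self.model = model
        self.delta = delta
        self.metric_kind = metric_kind
        self.fixed_metric = fixed_metric
        self.fixed_stepsize = fixed_stepsize
        self.adapt_metric = fixed_metric is None and metric_kind in ("diag", "dense")
        self.schedule = build_schedule(warmup, init_buffer, term_buffer, base_window)
        self.metric = fixed_metric if fixed_metric is not None else Metric.unit(model.dim)
        self._window: list[np.ndarray] = []
        self.da: DualAveragingState | None = None
        self.eps = fixed_stepsize if fixed_stepsize is not None else 1.0

    def start(self, q0: np.ndarray, rng: np.random.Generator) -> None:
        if self.fixed_stepsize is None:
            self.eps = find_reasonable_stepsize(self.model, q0, self.metric, rng)
            self.da = da_init(self.eps, self.delta)

    def update(self, it: int, q: np.ndarray, accept_stat: float, rng: np.random.Generator) -> None:
        """Process warmup iteration ``it`` (0-based) ending at state ``q``."""
        if self.da is not None:
            self.da = da_update(self.da, accept_stat)
            self.eps = math.exp(self.da.log_eps)
        if not self.adapt_metric:
            return
        sched = self.schedule
        in_slow = sched.init_buffer <= it < sched.warmup - sched.term_buffer
        if in_slow:
            self._window.append(np.asarray(q, dtype=float).copy())
        if it + 1 in sched.window_ends:
            self.metric = estimate_metric(np.array(self._window), self.metric_kind, prev=self.metric)
            self._window = []
            # Step size is re-found and dual averaging restarted at each
            # metric update except the last: the final window's metric
            # revision is typically small, and the long-running averaged
            # step size is a far better term-buffer anchor than a fresh
            # 50-iteration restart transient.
            is_last = (it + 1) == sched.window_ends[-1]
            if self.fixed_stepsize is None and not is_last:
                self.eps = find_reasonable_stepsize(self.model, q, self.metric, rng)
                self.da = da_init(self.eps, self.delta)

    def finish(self) -> None:
        """Freeze the sampling step size at the dual-averaging average."""
        if self.da is not None:
            self.eps = math.exp(self.da.log_eps_bar)
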