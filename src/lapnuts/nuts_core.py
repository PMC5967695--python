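"""One no-U-turn transition: leapfrog, recursive doubling, slice condition.

This is the slice-variable doubling variant of NUTS (the "algorithm 6"
formulation): a slice level is drawn under the initial energy, the
trajectory is doubled forward or backward until either end begins to turn
back (strict negative projection of the span on either end's velocity) or
the energy error exceeds ``DELTA_MAX``, and the next state is drawn
uniformly from the slice-valid leapfrog states.  The multinomial variant is
deliberately not implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metric import Metric
from .model_api import ModelPosterior

__all__ = [
    "PhasePoint",
    "TreeState",
    "TransitionInfo",
    "DELTA_MAX",
    "hamiltonian",
    "leapfrog",
    "is_uturn",
    "build_tree",
    "nuts_transition",
]

# Energy-error threshold flagging a divergent (integrator-failure) state.
DELTA_MAX = 1000.0


@dataclass
class PhasePoint:
    """Position/momentum pair with cached density and gradient."""

    q: np.ndarray
    p: np.ndarray
    logp: float
    grad: np.ndarray

    @classmethod
    def at(cls, q: np.ndarray, p: np.ndarray, model: ModelPosterior) -> "PhasePoint":
        lp, g = model.logp_grad(q)
        return cls(np.asarray(q, float), np.asarray(p, float), float(lp), np.asarray(g, float))


@dataclass
class TreeState:
    """State of a (sub)tree during doubling."""

    left: PhasePoint
    right: PhasePoint
    proposal: PhasePoint
    n_valid: int
    stop: bool
    divergent: bool
    sum_accept: float
    n_accept: int
    n_leapfrog: int


@dataclass
class TransitionInfo:
    """Per-iteration sampler metadata (the Stan-CSV column semantics)."""

    accept_stat: float
    stepsize: float
    treedepth: int
    n_leapfrog: int
    divergent: int
    energy: float
    logp: float = math.nan  # log density at the selected draw (lp__ column)


def hamiltonian(pt: PhasePoint, metric: Metric) -> float:
    """Total energy H = -log p(q) + p' M^-1 p / 2 (+inf if density is not)."""
    if not math.isfinite(pt.logp):
        return math.inf
    return -pt.logp + metric.kinetic(pt.p)


def leapfrog(pt: PhasePoint, eps: float, metric: Metric, model: ModelPosterior) -> PhasePoint:
    """One leapfrog step of size ``eps`` (negative for backward integration)."""
    p_half = pt.p + 0.5 * eps * pt.grad
    q_new = pt.q + eps * metric.velocity(p_half)
    lp, grad = model.logp_grad(q_new)
    if not np.all(np.isfinite(grad)) or not math.isfinite(lp):
        # divergent phase point: density treated as -inf
        return PhasePoint(q_new, p_half, -math.inf, np.zeros_like(q_new))
    p_new = p_half + 0.5 * eps * grad
    return PhasePoint(q_new, p_new, float(lp), np.asarray(grad, float))


def is_uturn(left: PhasePoint, right: PhasePoint, metric: Metric) -> bool:
    """No-U-turn termination: span projects negatively on either end velocity.

    Strict inequality: a zero projection (e.g. coincident ends) continues
    the trajectory.
    """
    dq = right.q - left.q
    return bool(dq @ metric.velocity(left.p) < 0.0 or dq @ metric.velocity(right.p) < 0.0)


def build_tree(
    pt: PhasePoint,
    log_u: float,
    direction: int,
    depth: int,
    eps: float,
    metric: Metric,
    model: ModelPosterior,
    H0: float,
    rng: np.random.Generator,
) -> TreeState:
    """Recursively build a subtree of 2**depth leapfrog states.

    ``log_u`` is the log of the slice variable; a state with energy H is
    slice-valid iff log_u <= -H and divergent iff log_u - DELTA_MAX > -H.
    The proposal is drawn uniformly among the subtree's valid states.
    """
    if depth == 0:
        new = leapfrog(pt, direction * eps, metric, model)
        H = hamiltonian(new, metric)
        n_valid = 1 if log_u <= -H else 0
        divergent = log_u - DELTA_MAX > -H
        accept = min(1.0, math.exp(min(0.0, H0 - H))) if math.isfinite(H) else 0.0
        return TreeState(
            left=new, right=new, proposal=new, n_valid=n_valid,
            stop=divergent, divergent=divergent,
            sum_accept=accept, n_accept=1, n_leapfrog=1,
        )

    first = build_tree(pt, log_u, direction, depth - 1, eps, metric, model, H0, rng)
    if first.stop:
        return first
    edge = first.right if direction == 1 else first.left
    second = build_tree(edge, log_u, direction, depth - 1, eps, metric, model, H0, rng)

    if direction == 1:
        left, right = first.left, second.right
    else:
        left, right = second.left, first.right
    n_total = first.n_valid + second.n_valid
    proposal = first.proposal
    if n_total > 0 and rng.random() < second.n_valid / n_total:
        proposal = second.proposal
    stop = second.stop or is_uturn(left, right, metric)
    return TreeState(
        left=left, right=right, proposal=proposal, n_valid=n_total,
        stop=stop, divergent=first.divergent or second.divergent,
        sum_accept=first.sum_accept + second.sum_accept,
        n_accept=first.n_accept + second.n_accept,
        n_leapfrog=first.n_leapfrog + second.n_leapfrog,
    )


def nuts_transition(
    q0: np.ndarray,
    eps: float,
    metric: Metric,
    model: ModelPosterior,
    max_treedepth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, TransitionInfo]:
    """One full NUTS update from ``q0`` at fixed step size ``eps``.

    Momentum is refreshed from N(0, M); the trajectory doubles until a
    U-turn, a divergence, or ``max_treedepth`` doublings.  Returns the new
    position and the iteration metadata.  ``accept_stat`` averages
    min(1, exp(H0 - H)) over every leapfrog state of the trajectory.
    """
    q0 = np.asarray(q0, dtype=float)
    start = PhasePoint.at(q0, metric.sample_momentum(rng), model)
    if not math.isfinite(start.logp):
        raise ValueError("non-finite log density at the current chain state")
    H0 = hamiltonian(start, metric)
    # u ~ Uniform(0, exp(-H0)) on the log scale
    log_u = math.log(rng.random()) - H0

    left = start
    right = start
    sample = start
    n_valid = 1
    depth = 0
    divergent = False
    sum_accept = 0.0
    n_accept = 0
    n_leapfrog = 0

    # Doubling: the subtree built at iteration j has depth j (2**j states),
    # so the reported treedepth is the depth of the deepest subtree built
    # and max_treedepth=0 forces exactly one leapfrog step.
    while True:
        direction = 1 if rng.random() < 0.5 else -1
        edge = right if direction == 1 else left
        subtree = build_tree(edge, log_u, direction, depth, eps, metric, model, H0, rng)
        sum_accept += subtree.sum_accept
        n_accept += subtree.n_accept
        n_leapfrog += subtree.n_leapfrog
        divergent = divergent or subtree.divergent
        if direction == 1:
            right = subtree.right
        else:
            left = subtree.left
        if not subtree.stop:
            if subtree.n_valid > 0 and rng.random() < subtree.n_valid / max(n_valid, 1):
                sample = subtree.proposal
        n_valid += subtree.n_valid
        if subtree.stop or is_uturn(left, right, metric):
            break
        if depth >= max_treedepth:
            break
        depth += 1

    energy = hamiltonian(sample, metric)
    info = TransitionInfo(
        accept_stat=sum_accept / max(n_accept, 1),
        stepsize=float(eps),
        treedepth=depth,
        n_leapfrog=n_leapfrog,
        divergent=int(divergent),
        energy=float(energy),
        logp=float(sample.logp),
    )
    return sample.q.copy(), info
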