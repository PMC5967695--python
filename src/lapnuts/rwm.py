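"""Random-walk Metropolis: the legacy sampler and a correctness oracle.

A multivariate-normal proposal scaled by 2.38-style optimal scaling around
a user (or mode-based) covariance.  Kept deliberately non-adaptive: its
role is cross-validating NUTS moments on analytic targets and providing
the historical mode-centred workflow.
"""

from __future__ import annotations

import math

import numpy as np

from .model_api import ModelPosterior

__all__ = ["rwm_transition", "default_scale"]


def default_scale(dim: int) -> float:
    """Classical optimal RWM scaling 2.4 / sqrt(dim)."""
    return 2.4 / math.sqrt(dim)


def rwm_transition(
    q0: np.ndarray,
    logp0: float,
    chol_cov: np.ndarray,
    scale: float,
    model: ModelPosterior,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """One Metropolis update with proposal q0 + scale * L @ z.

    ``chol_cov`` is the lower Cholesky factor of the proposal covariance.
    Returns (new position, new log density, accepted flag).
    """
    if not math.isfinite(logp0):
        raise ValueError("non-finite log density at the current chain state")
    q0 = np.asarray(q0, dtype=float)
    z = rng.standard_normal(q0.size)
    q_star = q0 + scale * (chol_cov @ z)
    logp_star = model.logp(q_star)
    if math.log(rng.random()) < logp_star - logp0:
        return q_star, float(logp_star), 1
    return q0.copy(), float(logp0), 0
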