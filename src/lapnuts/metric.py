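"""Mass matrix (metric) for the Hamiltonian dynamic.

The canonical stored quantity is the *inverse* mass matrix, i.e. the scale
on which the target's covariance is estimated during warmup: momentum is
drawn from N(0, M) and the kinetic energy is p' M^-1 p / 2, so a good M^-1
approximates the posterior covariance.  Constructors accept either
representation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Metric"]


class Metric:
    """Unit, diagonal or dense mass matrix with cached factorizations.

    Parameters
    ----------
    kind : {"unit", "diag", "dense"}
    inv_mass : vector (diag) or SPD matrix (dense)
        The inverse mass matrix M^-1 (posterior-covariance scale).
    """

    def __init__(self, kind: str, inv_mass=None, dim: int | None = None):
        if kind not in ("unit", "diag", "dense"):
            raise ValueError(f"unknown metric kind {kind!r}")
        self.kind = kind
        if kind == "unit":
            if dim is None:
                raise ValueError("unit metric requires dim")
            self.dim = dim
            self.inv_mass = None
        elif kind == "diag":
            v = np.asarray(inv_mass, dtype=float)
            if v.ndim != 1 or np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError("diagonal inverse mass must be a positive finite vector")
            self.dim = v.size
            self.inv_mass = v
            self._sqrt_inv = np.sqrt(v)
        else:
            A = np.asarray(inv_mass, dtype=float)
            if A.ndim != 2 or A.shape[0] != A.shape[1]:
                raise ValueError("dense inverse mass must be square")
            A = 0.5 * (A + A.T)
            # raises LinAlgError if not SPD
            self._chol = np.linalg.cholesky(A)
            self.dim = A.shape[0]
            self.inv_mass = A

    # -- constructors ------------------------------------------------------
    @classmethod
    def unit(cls, dim: int) -> "Metric":
        return cls("unit", dim=dim)

    @classmethod
    def diag(cls, inv_mass_diag) -> "Metric":
        return cls("diag", inv_mass=inv_mass_diag)

    @classmethod
    def dense(cls, inv_mass) -> "Metric":
        return cls("dense", inv_mass=inv_mass)

    @classmethod
    def from_mass_diag(cls, mass_diag) -> "Metric":
        """Diagonal metric given the mass matrix diagonal M."""
        return cls("diag", inv_mass=1.0 / np.asarray(mass_diag, dtype=float))

    @classmethod
    def from_mass_dense(cls, mass) -> "Metric":
        """Dense metric given the mass matrix M."""
        return cls("dense", inv_mass=np.linalg.inv(np.asarray(mass, dtype=float)))

    # -- operations --------------------------------------------------------
    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        """Draw p ~ N(0, M)."""
        z = rng.standard_normal(self.dim)
        if self.kind == "unit":
            return z
        if self.kind == "diag":
            return z / self._sqrt_inv
        # M = (L L')^-1 with L = chol(M^-1): p = L^-T z has covariance M
        return np.linalg.solve(self._chol.T, z)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        """M^-1 p — the velocity used in leapfrog drift and U-turn checks."""
        if self.kind == "unit":
            return p
        if self.kind == "diag":
            return self.inv_mass * p
        return self.inv_mass @ p

    def kinetic(self, p: np.ndarray) -> float:
        # overflow to +inf is fine: the state is then treated as divergent
        with np.errstate(over="ignore"):
            return 0.5 * float(p @ self.velocity(p))
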