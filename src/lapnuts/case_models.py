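"""Case-study models and synthetic-data generators.

Two hierarchical ecological models drive the package's end-to-end testing:

* ``wildflower`` — a binomial GLMM for flowering success of a perennial
  plant, with year intercepts, plant intercepts and plant slopes as three
  random-effect components (the two plant-indexed components are crossed
  with year through the observation layout).
* ``swallows`` — a Cormack–Jolly–Seber style mark–recapture model of
  juvenile survival and detection with environmental covariates and three
  random-effect components (brood effects on survival, brood effects on
  detection, year effects on survival).  The latent alive states are
  marginalized analytically with the standard chi recursion, so the model
  exposes a smooth log density suitable for gradient-based sampling.

Hypervariances are sampled on the log scale with the Jacobian adjustment
included directly in the density, and the random effects use non-centered
parameterization (effect = sigma * raw, raw ~ N(0,1)) by default.  Priors
are weakly informative: N(0, 5^2) on fixed effects, half-N(0, 5^2) on the
standard deviations.

Also provided: analytic test targets (multivariate normal, Neal's funnel
in centered and non-centered form) and three small random-effect models
used to validate the Laplace machinery (linear-Gaussian, Poisson
log-normal, Bernoulli random-intercept GLMM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .model_api import ModelPosterior, ParameterSpec

__all__ = [
    "mvn_model",
    "funnel_model",
    "linear_gaussian_model",
    "poisson_lognormal_model",
    "gen_bernoulli_glmm",
    "bernoulli_glmm_model",
    "WildflowerData",
    "gen_wildflower",
    "wildflower_model",
    "SwallowsData",
    "gen_swallows",
    "swallows_model",
    "get_model",
    "MODEL_REGISTRY",
]

_PRIOR_SD = 5.0  # fixed effects N(0, 5^2); sigmas half-N(0, 5^2)

# beyond this the exp of a log-scale parameter overflows; the density is
# treated as -inf and the sampler flags the trajectory as divergent
_Q_LIMIT = 200.0


def _out_of_range(q: np.ndarray) -> bool:
    return bool(np.max(np.abs(q)) > _Q_LIMIT) or not np.all(np.isfinite(q))


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _halfnormal_logpdf_with_jacobian(log_sigma: float, sd: float = _PRIOR_SD) -> tuple[float, float]:
    """log prior of sigma ~ half-N(0, sd^2) sampled as log sigma.

    Returns (log density + Jacobian log sigma, gradient wrt log sigma).
    """
    sigma = math.exp(log_sigma)
    lp = -0.5 * sigma * sigma / (sd * sd) + log_sigma
    dlp = -sigma * sigma / (sd * sd) + 1.0
    return lp, dlp


# ---------------------------------------------------------------------------
# analytic targets
# ---------------------------------------------------------------------------

def mvn_model(mean, cov) -> ModelPosterior:
    """Multivariate normal target with exact density and gradient."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be symmetric positive definite") from exc
    prec = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    const = -0.5 * (mean.size * math.log(2.0 * math.pi) + logdet)
    specs = [ParameterSpec(f"x{i}") for i in range(mean.size)]

    class _MVN(ModelPosterior):
        def logp_grad(self, q):
            d = np.asarray(q, float) - mean
            g = -prec @ d
            return const + 0.5 * float(d @ g), g

    return _MVN(specs, name="mvn")


def funnel_model(dim: int = 2, centered: bool = True) -> ModelPosterior:
    """Neal's funnel: v ~ N(0, 3^2), x_i | v ~ N(0, e^v), i = 1..dim-1.

    The centered form is the classic pathological geometry; the
    non-centered form samples z_i = x_i e^{-v/2} ~ N(0,1), an easy target
    defining the same joint law of (v, x).
    """
    if dim < 2:
        raise ValueError("funnel requires dim >= 2")
    k = dim - 1
    specs = [ParameterSpec("v")] + [
        ParameterSpec(f"x{i}" if centered else f"z{i}") for i in range(k)
    ]

    class _FunnelC(ModelPosterior):
        def logp_grad(self, q):
            if _out_of_range(q):
                return -math.inf, np.zeros(len(q))
            v, x = q[0], q[1:]
            ev = math.exp(-v)
            ss = float(x @ x)
            lp = -v * v / 18.0 - 0.5 * k * v - 0.5 * ev * ss
            g = np.empty(dim)
            g[0] = -v / 9.0 - 0.5 * k + 0.5 * ev * ss
            g[1:] = -x * ev
            return lp, g

    class _FunnelNC(ModelPosterior):
        def logp_grad(self, q):
            v, z = q[0], q[1:]
            lp = -v * v / 18.0 - 0.5 * float(z @ z)
            g = np.empty(dim)
            g[0] = -v / 9.0
            g[1:] = -z
            return lp, g

    return (_FunnelC if centered else _FunnelNC)(specs, name="funnel" if centered else "funnel_nc")


# ---------------------------------------------------------------------------
# small random-effect models for the Laplace machinery
# ---------------------------------------------------------------------------

def linear_gaussian_model(y, sigma_u: float, sigma_y: float, prior_sd: float = 10.0) -> ModelPosterior:
    """theta ~ N(0, prior_sd^2); u ~ N(0, sigma_u^2); y_j | theta,u ~ N(theta+u, sigma_y^2).

    The Laplace approximation is exact here, which makes this the keystone
    target for marginalization tests: the marginal over u has the closed
    form N(y; theta, sigma_y^2 I + sigma_u^2 11').
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    specs = [ParameterSpec("theta", role="fixed"), ParameterSpec("u", role="random")]
    c = -0.5 * math.log(2 * math.pi * prior_sd**2) - 0.5 * math.log(2 * math.pi * sigma_u**2) \
        - 0.5 * n * math.log(2 * math.pi * sigma_y**2)

    class _LG(ModelPosterior):
        def logp_grad(self, q):
            theta, u = q
            r = y - theta - u
            lp = c - 0.5 * theta**2 / prior_sd**2 - 0.5 * u**2 / sigma_u**2 \
                - 0.5 * float(r @ r) / sigma_y**2
            s = float(r.sum()) / sigma_y**2
            g = np.array([-theta / prior_sd**2 + s, -u / sigma_u**2 + s])
            return lp, g

        def uu_hessian(self, q, random_index):
            return np.array([[1.0 / sigma_u**2 + n / sigma_y**2]])

    return _LG(specs, name="linear_gaussian")


def poisson_lognormal_model(y, sigma_u: float, prior_sd: float = _PRIOR_SD) -> ModelPosterior:
    """theta ~ N(0, prior_sd^2); u ~ N(0, sigma_u^2); y_j ~ Poisson(exp(theta + u)).

    A single log-normal random intercept: the marginal over u has no closed
    form, so adaptive Gauss-Hermite quadrature serves as the oracle.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ysum = float(y.sum())
    c = -float(gammaln(y + 1).sum()) - 0.5 * math.log(2 * math.pi * sigma_u**2) \
        - 0.5 * math.log(2 * math.pi * prior_sd**2)
    specs = [ParameterSpec("theta", role="fixed"), ParameterSpec("u", role="random")]

    class _PLN(ModelPosterior):
        def logp_grad(self, q):
            if _out_of_range(q):
                return -math.inf, np.zeros(len(q))
            theta, u = q
            lam = math.exp(theta + u)
            lp = c + ysum * (theta + u) - n * lam - 0.5 * u**2 / sigma_u**2 \
                - 0.5 * theta**2 / prior_sd**2
            g = np.array([
                ysum - n * lam - theta / prior_sd**2,
                ysum - n * lam - u / sigma_u**2,
            ])
            return lp, g

        def uu_hessian(self, q, random_index):
            theta, u = q
            return np.array([[n * math.exp(theta + u) + 1.0 / sigma_u**2]])

    return _PLN(specs, name="poisson_lognormal")


def gen_bernoulli_glmm(
    n_groups: int = 40,
    obs_per_group: int = 2,
    beta0: float = 0.0,
    sigma: float = 1.5,
    seed: int = 0,
):
    """Binary observations with a group random intercept on the logit scale.

    The few-observations-per-group regime (the default: 2 Bernoulli trials
    per group) is the classic setting in which the Laplace approximation
    of the random-effect integral is inaccurate.
    Returns (successes per group, trials per group).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma, size=n_groups)
    p = expit(beta0 + u)
    k = rng.binomial(obs_per_group, p)
    n = np.full(n_groups, obs_per_group)
    return k, n


def bernoulli_glmm_model(k, n, prior_sd: float = _PRIOR_SD) -> ModelPosterior:
    """Random-intercept logistic GLMM, non-centered, sigma in log space.

    Parameters: beta0, log sigma (fixed) and one raw N(0,1) deviate per
    group (random).  eta_g = beta0 + sigma * u_g.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    G = k.size
    if np.any(k > n):
        raise ValueError("successes exceed trials")
    binom_c = float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)).sum())
    specs = [ParameterSpec("beta0"), ParameterSpec("log_sigma")] + [
        ParameterSpec(f"u_raw[{g}]", role="random") for g in range(G)
    ]

    class _GLMM(ModelPosterior):
        def logp_grad(self, q):
            if _out_of_range(q):
                return -math.inf, np.zeros(len(q))
            beta0, log_sigma = q[0], q[1]
            u = q[2:]
            sigma = math.exp(log_sigma)
            eta = beta0 + sigma * u
            lp = binom_c + float(k @ eta) - float(n @ np.logaddexp(0.0, eta)) \
                - 0.5 * float(u @ u) - 0.5 * beta0**2 / prior_sd**2
            lp_s, dlp_s = _halfnormal_logpdf_with_jacobian(log_sigma, prior_sd)
            lp += lp_s
            r = k - n * expit(eta)
            g = np.empty(G + 2)
            g[0] = float(r.sum()) - beta0 / prior_sd**2
            g[1] = sigma * float(r @ u) + dlp_s
            g[2:] = sigma * r - u
            return lp, g

        def uu_hessian(self, q, random_index):
            beta0, log_sigma = q[0], q[1]
            u = q[2:]
            sigma = math.exp(log_sigma)
            p = expit(beta0 + sigma * u)
            return np.diag(sigma**2 * n * p * (1.0 - p) + 1.0)

    m = _GLMM(specs, name="bernoulli_glmm")
    m.fixed_effect_names = ["beta0"]
    m.hyper_names = ["log_sigma"]
    return m


# ---------------------------------------------------------------------------
# wildflower: binomial GLMM with three random-effect components
# ---------------------------------------------------------------------------

@dataclass
class WildflowerData:
    """Observation-level flowering records.

    Each record is one plant-year: ``trials`` flowering opportunities with
    ``successes`` successes, a standardized ``size`` covariate, and plant /
    year grouping ids.
    """

    n_plants: int
    n_years: int
    plant: np.ndarray
    year: np.ndarray
    trials: np.ndarray
    successes: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.successes > self.trials) or np.any(self.successes < 0):
            raise ValueError("need 0 <= successes <= trials")
        if self.plant.max() >= self.n_plants or self.year.max() >= self.n_years:
            raise ValueError("group id out of range")


def gen_wildflower(
    n_plants: int = 40,
    n_years: int = 6,
    trials_per_obs: int = 4,
    params: dict | None = None,
    seed: int = 0,
) -> WildflowerData:
    """Simulate flowering-success data from the wildflower GLMM.

    One observation per plant-year.  Success probability is
    logistic(beta0 + (beta_size + slope_i) * size + year_j + plant_i) with
    year intercepts ~ N(0, sigma_year^2), plant intercepts
    ~ N(0, sigma_plant_int^2) and plant slopes ~ N(0, sigma_plant_slope^2);
    the size covariate is standardized to mean 0, sd 1.
    """
    if n_plants <= 0 or n_years <= 0 or trials_per_obs <= 0:
        raise ValueError("dimensions must be positive")
    defaults = dict(beta0=-0.5, beta_size=0.8, sigma_year=0.7,
                    sigma_plant_int=1.0, sigma_plant_slope=0.5)
    if params:
        defaults.update(params)
    p = defaults
    for key in ("sigma_year", "sigma_plant_int", "sigma_plant_slope"):
        if p[key] < 0:
            raise ValueError(f"{key} must be nonnegative")
    rng = np.random.default_rng(seed)
    plant = np.repeat(np.arange(n_plants), n_years)
    year = np.tile(np.arange(n_years), n_plants)
    size = rng.normal(size=plant.size)
    size = (size - size.mean()) / size.std()
    year_eff = rng.normal(0.0, p["sigma_year"], size=n_years)
    plant_int = rng.normal(0.0, p["sigma_plant_int"], size=n_plants)
    plant_slope = rng.normal(0.0, p["sigma_plant_slope"], size=n_plants)
    eta = (p["beta0"] + (p["beta_size"] + plant_slope[plant]) * size
           + year_eff[year] + plant_int[plant])
    successes = rng.binomial(trials_per_obs, expit(eta))
    return WildflowerData(
        n_plants=n_plants, n_years=n_years, plant=plant, year=year,
        trials=np.full(plant.size, trials_per_obs), successes=successes, size=size,
    )


def wildflower_model(data: WildflowerData, prior_sd: float = _PRIOR_SD,
                     non_centered: bool = True) -> ModelPosterior:
    """Binomial GLMM with year intercepts, plant intercepts and plant slopes.

    Parameter order: beta0, beta_size, log sigma_year, log sigma_plant_int,
    log sigma_plant_slope, then the three raw random-effect vectors
    (year, plant intercept, plant slope), for 5 + n_years + 2*n_plants
    parameters in total.
    """
    ny, npl = data.n_years, data.n_plants
    k = data.successes.astype(float)
    n = data.trials.astype(float)
    x = data.size
    plant, year = data.plant, data.year
    binom_c = float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)).sum())

    fixed_names = ["beta0", "beta_size"]
    hyper_names = ["log_sigma_year", "log_sigma_plant_int", "log_sigma_plant_slope"]
    re_names = ([f"year_raw[{j}]" for j in range(ny)]
                + [f"plant_int_raw[{i}]" for i in range(npl)]
                + [f"plant_slope_raw[{i}]" for i in range(npl)])
    specs = [ParameterSpec(nm) for nm in fixed_names + hyper_names] + [
        ParameterSpec(nm, role="random") for nm in re_names
    ]
    s0 = 5            # start of REs
    s1 = s0 + ny      # start of plant intercepts
    s2 = s1 + npl     # start of plant slopes
    d = s2 + npl

    class _WFnc(ModelPosterior):
        def logp_grad(self, q):
            if _out_of_range(q):
                return -math.inf, np.zeros(len(q))
            b0, bx = q[0], q[1]
            sy, sp, ss = math.exp(q[2]), math.exp(q[3]), math.exp(q[4])
            yr = q[s0:s1]
            pi = q[s1:s2]
            sl = q[s2:d]
            eta = b0 + (bx + ss * sl[plant]) * x + sy * yr[year] + sp * pi[plant]
            lp = binom_c + float(k @ eta) - float(n @ np.logaddexp(0.0, eta))
            lp -= 0.5 * (float(yr @ yr) + float(pi @ pi) + float(sl @ sl))
            lp -= 0.5 * (b0 * b0 + bx * bx) / prior_sd**2
            dh = np.empty(3)
            for j, lsig in enumerate((q[2], q[3], q[4])):
                lp_s, dh[j] = _halfnormal_logpdf_with_jacobian(lsig, prior_sd)
                lp += lp_s
            r = k - n * expit(eta)
            g = np.empty(d)
            g[0] = float(r.sum()) - b0 / prior_sd**2
            g[1] = float(r @ x) - bx / prior_sd**2
            g[2] = sy * float(r @ yr[year]) + dh[0]
            g[3] = sp * float(r @ pi[plant]) + dh[1]
            g[4] = ss * float((r * x) @ sl[plant]) + dh[2]
            g[s0:s1] = sy * np.bincount(year, weights=r, minlength=ny) - yr
            g[s1:s2] = sp * np.bincount(plant, weights=r, minlength=npl) - pi
            g[s2:d] = ss * np.bincount(plant, weights=r * x, minlength=npl) - sl
            return lp, g

        def uu_hessian(self, q, random_index):
            sy, sp, ss = math.exp(q[2]), math.exp(q[3]), math.exp(q[4])
            b0, bx = q[0], q[1]
            yr, pi, sl = q[s0:s1], q[s1:s2], q[s2:d]
            eta = b0 + (bx + ss * sl[plant]) * x + sy * yr[year] + sp * pi[plant]
            w = n * expit(eta) * (1.0 - expit(eta))
            nre = ny + 2 * npl
            Z = np.zeros((k.size, nre))
            rows = np.arange(k.size)
            Z[rows, year] = sy
            Z[rows, ny + plant] = sp
            Z[rows, ny + npl + plant] = ss * x
            return Z.T @ (w[:, None] * Z) + np.eye(nre)

    class _WFc(ModelPosterior):
        # centered variant: effects enter directly with N(0, sigma^2) priors
        def logp_grad(self, q):
            if _out_of_range(q):
                return -math.inf, np.zeros(len(q))
            b0, bx = q[0], q[1]
            sy, sp, ss = math.exp(q[2]), math.exp(q[3]), math.exp(q[4])
            yr = q[s0:s1]
            pi = q[s1:s2]
            sl = q[s2:d]
            eta = b0 + (bx + sl[plant]) * x + yr[year] + pi[plant]
            lp = binom_c + float(k @ eta) - float(n @ np.logaddexp(0.0, eta))
            lp -= 0.5 * float(yr @ yr) / sy**2 + ny * math.log(sy)
            lp -= 0.5 * float(pi @ pi) / sp**2 + npl * math.log(sp)
            lp -= 0.5 * float(sl @ sl) / ss**2 + npl * math.log(ss)
            lp -= 0.5 * (b0 * b0 + bx * bx) / prior_sd**2
            dh = np.empty(3)
            for j, lsig in enumerate((q[2], q[3], q[4])):
                lp_s, dh[j] = _halfnormal_logpdf_with_jacobian(lsig, prior_sd)
                lp += lp_s
            r = k - n * expit(eta)
            g = np.empty(d)
            g[0] = float(r.sum()) - b0 / prior_sd**2
            g[1] = float(r @ x) - bx / prior_sd**2
            g[2] = float(yr @ yr) / sy**2 - ny + dh[0]
            g[3] = float(pi @ pi) / sp**2 - npl + dh[1]
            g[4] = float(sl @ sl) / ss**2 - npl + dh[2]
            g[s0:s1] = np.bincount(year, weights=r, minlength=ny) - yr / sy**2
            g[s1:s2] = np.bincount(plant, weights=r, minlength=npl) - pi / sp**2
            g[s2:d] = np.bincount(plant, weights=r * x, minlength=npl) - sl / ss**2
            return lp, g

    m = (_WFnc if non_centered else _WFc)(specs, name="wildflower")
    m.fixed_effect_names = fixed_names + hyper_names
    m.hyper_names = hyper_names
    return m


# ---------------------------------------------------------------------------
# swallows: CJS mark-recapture with three random-effect components
# ---------------------------------------------------------------------------

@dataclass
class SwallowsData:
    """Capture histories with covariates and grouping structure.

    ``histories`` is a 0/1 matrix (individuals x occasions); ``first`` /
    ``last`` give each individual's first and last detection occasion
    (0-based, first <= last).  ``env`` is an occasion-interval covariate on
    survival, ``effort`` an occasion covariate on detection, both
    standardized.
    """

    n_individuals: int
    n_occasions: int
    n_broods: int
    n_years: int
    histories: np.ndarray
    first: np.ndarray
    last: np.ndarray
    size: np.ndarray
    env: np.ndarray
    effort: np.ndarray
    brood: np.ndarray
    year: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isin(self.histories, (0, 1))):
            raise ValueError("capture histories must be binary")
        if np.any(self.first > self.last):
            raise ValueError("first capture must precede last capture")


def gen_swallows(config: dict | None = None, seed: int = 0) -> SwallowsData:
    """Simulate mark-recapture histories from the state-space model.

    Individuals (default 2 per brood) are released at a random occasion,
    survive each interval with probability
    logistic(b0 + b_env*env_t + b_size*size_i + brood and year effects)
    and, while alive, are detected with probability
    logistic(a0 + a_eff*effort_t + brood effect).  Histories start at the
    release occasion (CJS conditioning on first capture).
    """
    cfg = dict(n_broods=84, n_years=4, n_occasions=10, per_brood=2,
               b0=1.2, b_env=0.5, b_size=0.4, a0=0.6, a_eff=0.5,
               sigma_brood_phi=0.5, sigma_brood_p=0.7, sigma_year_phi=0.3)
    if config:
        cfg.update(config)
    if min(cfg["n_broods"], cfg["n_years"], cfg["n_occasions"], cfg["per_brood"]) <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    B, Y, K = cfg["n_broods"], cfg["n_years"], cfg["n_occasions"]
    N = B * cfg["per_brood"]
    brood = np.repeat(np.arange(B), cfg["per_brood"])
    year = brood % Y  # broods assigned to years round-robin
    size = rng.normal(size=N)
    size = (size - size.mean()) / size.std()
    env = rng.normal(size=K - 1)
    env = (env - env.mean()) / env.std()
    effort = rng.normal(size=K)
    effort = (effort - effort.mean()) / effort.std()
    re_bphi = rng.normal(0.0, cfg["sigma_brood_phi"], size=B)
    re_bp = rng.normal(0.0, cfg["sigma_brood_p"], size=B)
    re_yphi = rng.normal(0.0, cfg["sigma_year_phi"], size=Y)

    first = rng.integers(0, max(K - 2, 1), size=N)
    hist = np.zeros((N, K), dtype=int)
    hist[np.arange(N), first] = 1
    alive = np.ones(N, dtype=bool)
    for t in range(K - 1):
        started = first <= t
        phi = expit(cfg["b0"] + cfg["b_env"] * env[t] + cfg["b_size"] * size
                    + re_bphi[brood] + re_yphi[year])
        alive = alive & (~started | (rng.random(N) < phi))
        p = expit(cfg["a0"] + cfg["a_eff"] * effort[t + 1] + re_bp[brood])
        det = started & alive & (rng.random(N) < p)
        hist[det, t + 1] = 1
    last = np.array([np.max(np.nonzero(h)[0]) for h in hist])
    return SwallowsData(
        n_individuals=N, n_occasions=K, n_broods=B, n_years=Y,
        histories=hist, first=first, last=last, size=size,
        env=env, effort=effort, brood=brood, year=year,
    )


def swallows_model(data: SwallowsData, prior_sd: float = _PRIOR_SD,
                   non_centered: bool = True) -> ModelPosterior:
    """CJS survival/detection model with analytically marginalized states.

    The latent alive-state sequences are summed out with the chi recursion
    chi_t = (1 - phi_t) + phi_t (1 - p_{t+1}) chi_{t+1}, so the likelihood
    of a history is the product of its observed survival/detection terms
    times chi at the last detection.  Five fixed regression effects
    (survival: intercept, environmental slope, size slope; detection:
    intercept, effort slope), three log-scale hyper-SDs with Jacobian
    terms, and three non-centered random-effect vectors: brood-on-survival,
    brood-on-detection, year-on-survival.
    """
    N, K = data.n_individuals, data.n_occasions
    B, Y = data.n_broods, data.n_years
    y = data.histories.astype(float)
    first, last = data.first, data.last
    size, env, effort = data.size, data.env, data.effort
    brood, year = data.brood, data.year

    fixed_names = ["phi_intercept", "phi_env", "phi_size", "p_intercept", "p_effort"]
    hyper_names = ["log_sigma_brood_phi", "log_sigma_brood_p", "log_sigma_year_phi"]
    re_names = ([f"brood_phi_raw[{b}]" for b in range(B)]
                + [f"brood_p_raw[{b}]" for b in range(B)]
                + [f"year_phi_raw[{j}]" for j in range(Y)])
    specs = [ParameterSpec(nm) for nm in fixed_names + hyper_names] + [
        ParameterSpec(nm, role="random") for nm in re_names
    ]
    o0 = 8
    o1 = o0 + B
    o2 = o1 + B
    d = o2 + Y

    ts = np.arange(K - 1)
    # masks over the (individual, interval) and (individual, occasion) grids
    surv_mask = (first[:, None] <= ts) & (ts <= last[:, None] - 1)      # N x K-1
    det_mask = (first[:, None] + 1 <= np.arange(K)) & (np.arange(K) <= last[:, None])  # N x K
    chi_mask = ts >= last[:, None]                                      # N x K-1

    class _CJS(ModelPosterior):
        def logp_grad(self, q):
            if _out_of_range(q):
                return -math.inf, np.zeros(len(q))
            b0, benv, bsize, a0, aeff = q[:5]
            sbp, sbd, syp = math.exp(q[5]), math.exp(q[6]), math.exp(q[7])
            rbp = q[o0:o1]
            rbd = q[o1:o2]
            ryp = q[o2:d]
            if non_centered:
                ebphi = sbp * rbp
                ebp = sbd * rbd
                eyphi = syp * ryp
            else:
                ebphi, ebp, eyphi = rbp, rbd, ryp
            # logits: survival intervals (N x K-1), detection occasions (N x K)
            eta_phi = (b0 + benv * env[None, :] + bsize * size[:, None]
                       + ebphi[brood][:, None] + eyphi[year][:, None])
            eta_p = a0 + aeff * effort[None, :] + ebp[brood][:, None]
            phi = expit(eta_phi)
            p = expit(eta_p)

            # chi recursion, vectorized over individuals; chi can underflow
            # to 0 at extreme logits (phi, p -> 1), in which case the
            # density is -inf and the trajectory is flagged divergent
            chi = np.ones((N, K))
            for t in range(K - 2, -1, -1):
                chi[:, t] = (1.0 - phi[:, t]) + phi[:, t] * (1.0 - p[:, t + 1]) * chi[:, t + 1]
            if np.any(chi[np.arange(N), last] <= 0.0):
                return -math.inf, np.zeros(d)

            lp = float((surv_mask * _log_sigmoid(eta_phi)).sum())
            lp += float((det_mask * (y * _log_sigmoid(eta_p)
                                     + (1 - y) * _log_sigmoid(-eta_p))).sum())
            lp += float(np.log(chi[np.arange(N), last]).sum())

            # gradient wrt logits
            g_phi = surv_mask * (1.0 - phi)
            g_p = det_mask * (y - p)
            # backward-recursion sensitivities through chi
            c = np.zeros(N)
            for t in range(K - 1):
                at_last = last == t
                if at_last.any():
                    c = np.where(at_last, 1.0 / chi[:, t], c)
                live = chi_mask[:, t]
                dchi_dphi = -1.0 + (1.0 - p[:, t + 1]) * chi[:, t + 1]
                g_phi[:, t] += np.where(live, c * dchi_dphi * phi[:, t] * (1 - phi[:, t]), 0.0)
                g_p[:, t + 1] += np.where(
                    live, c * (-phi[:, t] * chi[:, t + 1]) * p[:, t + 1] * (1 - p[:, t + 1]), 0.0)
                c = c * phi[:, t] * (1.0 - p[:, t + 1])

            gphi_i = g_phi.sum(axis=1)   # per-individual survival-logit mass
            gp_i = g_p.sum(axis=1)
            g = np.empty(d)
            g[0] = float(gphi_i.sum()) - b0 / prior_sd**2
            g[1] = float(g_phi.sum(axis=0) @ env) - benv / prior_sd**2
            g[2] = float(gphi_i @ size) - bsize / prior_sd**2
            g[3] = float(gp_i.sum()) - a0 / prior_sd**2
            g[4] = float(g_p.sum(axis=0) @ effort) - aeff / prior_sd**2
            lp -= 0.5 * float(q[:5] @ q[:5]) / prior_sd**2

            bp_acc = np.bincount(brood, weights=gphi_i, minlength=B)
            bd_acc = np.bincount(brood, weights=gp_i, minlength=B)
            yp_acc = np.bincount(year, weights=gphi_i, minlength=Y)
            dh = np.empty(3)
            for j in range(3):
                lp_s, dh[j] = _halfnormal_logpdf_with_jacobian(q[5 + j], prior_sd)
                lp += lp_s
            if non_centered:
                lp -= 0.5 * (float(rbp @ rbp) + float(rbd @ rbd) + float(ryp @ ryp))
                g[5] = sbp * float(bp_acc @ rbp) + dh[0]
                g[6] = sbd * float(bd_acc @ rbd) + dh[1]
                g[7] = syp * float(yp_acc @ ryp) + dh[2]
                g[o0:o1] = sbp * bp_acc - rbp
                g[o1:o2] = sbd * bd_acc - rbd
                g[o2:d] = syp * yp_acc - ryp
            else:
                lp -= (0.5 * float(rbp @ rbp) / sbp**2 + B * math.log(sbp)
                       + 0.5 * float(rbd @ rbd) / sbd**2 + B * math.log(sbd)
                       + 0.5 * float(ryp @ ryp) / syp**2 + Y * math.log(syp))
                g[5] = float(rbp @ rbp) / sbp**2 - B + dh[0]
                g[6] = float(rbd @ rbd) / sbd**2 - B + dh[1]
                g[7] = float(ryp @ ryp) / syp**2 - Y + dh[2]
                g[o0:o1] = bp_acc - rbp / sbp**2
                g[o1:o2] = bd_acc - rbd / sbd**2
                g[o2:d] = yp_acc - ryp / syp**2
            return lp, g

    m = _CJS(specs, name="swallows")
    m.fixed_effect_names = fixed_names
    m.hyper_names = hyper_names
    return m


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _build_mvn(**cfg):
    dim = int(cfg.get("dim", 2))
    rho = float(cfg.get("rho", 0.8))
    cov = rho * np.ones((dim, dim)) + (1 - rho) * np.eye(dim)
    return mvn_model(np.zeros(dim), cov)

def _build_funnel(**cfg):
    return funnel_model(int(cfg.get("dim", 2)), centered=bool(cfg.get("centered", True)))

def _build_wildflower(**cfg):
    seed = int(cfg.pop("seed", 0))
    nc = bool(cfg.pop("non_centered", True))
    data = gen_wildflower(seed=seed, **cfg)
    return wildflower_model(data, non_centered=nc)

def _build_swallows(**cfg):
    seed = int(cfg.pop("seed", 0))
    nc = bool(cfg.pop("non_centered", True))
    data = gen_swallows(cfg or None, seed=seed)
    return swallows_model(data, non_centered=nc)

def _build_glmm(**cfg):
    seed = int(cfg.pop("seed", 0))
    k, n = gen_bernoulli_glmm(seed=seed, **cfg)
    return bernoulli_glmm_model(k, n)


MODEL_REGISTRY = {
    "mvn": _build_mvn,
    "funnel": _build_funnel,
    "wildflower": _build_wildflower,
    "swallows": _build_swallows,
    "glmm": _build_glmm,
}


def get_model(name: str, **config) -> ModelPosterior:
    """Build a registered model fixture by name with keyword configuration."""
    try:
        builder = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}") from None
    return builder(**config)
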