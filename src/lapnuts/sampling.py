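"""Multi-chain orchestration, chain persistence and sample extraction.

``sample`` wires the NUTS transition and the warmup adapter (or the RWM
fallback) into reproducible multi-chain runs.  Each chain's pseudo-random
stream is seeded from (global seed, chain index), so results are
bit-identical regardless of serial or parallel execution and of
scheduling order.  Defaults follow the conventional self-tuning setup:
3 chains, 2000 iterations of which 1000 are warmup, target acceptance
0.8, adapted step size and adapted diagonal mass matrix.

Chains persist in a Stan-CSV-compatible dialect: '#'-prefixed header
comments carrying the run configuration, one name row, then one row per
iteration with lp__ and the sampler metadata columns before the
parameters.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation import WarmupAdapter
from .metric import Metric
from .model_api import ModelPosterior, find_mode
from .nuts_core import TransitionInfo, nuts_transition
from .rwm import default_scale, rwm_transition
from .transforms import BoundKind, constrain

__all__ = ["RunConfig", "ChainOutput", "SamplerFit", "sample", "rwm_chain",
           "extract_samples", "extract_sampler_params",
           "write_chain_csv", "read_chain_csv", "benchmark"]

NUTS_COLUMNS = ["accept_stat__", "stepsize__", "treedepth__", "n_leapfrog__",
                "divergent__", "energy__"]
RWM_COLUMNS = ["accept_stat__", "accepted__"]


@dataclass
class RunConfig:
    """Run settings mirroring the sampler front-end signature."""

    model: str = ""
    model_config: dict = field(default_factory=dict)
    algorithm: str = "nuts"
    chains: int = 3
    iter: int = 2000
    warmup: int = 1000
    seed: int = 1
    adapt_delta: float = 0.8
    max_treedepth: int = 12
    metric: str = "diag"           # unit | diag | dense | auto
    metric_file: str | None = None
    stepsize: float | None = None
    laplace: bool = False
    parallel: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not self.warmup < self.iter:
            raise ValueError("warmup must be smaller than iter")


@dataclass
class ChainOutput:
    """Draws plus per-iteration sampler metadata for one chain."""

    chain_id: int
    draws: np.ndarray                 # iter x dim, unconstrained scale
    sampler_params: dict              # column -> array of length iter
    lp: np.ndarray                    # log density per iteration
    warmup: int
    param_names: list
    algorithm: str = "nuts"
    stepsize: float = math.nan        # frozen sampling step size
    metric_kind: str = "diag"
    inv_mass: np.ndarray | None = None
    seed: int = 0
    wall_time: float = math.nan

    @property
    def n_iter(self) -> int:
        return self.draws.shape[0]


def _constrain_draws(draws: np.ndarray, specs) -> np.ndarray:
    """Vectorized constrained view of an iterations-by-dim draw matrix."""
    out = draws.copy()
    for j, s in enumerate(specs):
        b = s.bound
        k = b.kind
        if k == "unbounded":
            continue
        col = draws[:, j]
        if k == "lower-only":
            out[:, j] = b.lower + np.exp(col)
        elif k == "upper-only":
            out[:, j] = b.upper - np.exp(col)
        else:
            w = b.upper - b.lower
            out[:, j] = b.lower + w / (1.0 + np.exp(-col))
    return out


class SamplerFit:
    """Collection of chains from one run, with extraction helpers."""

    def __init__(self, chains: list[ChainOutput], model: ModelPosterior | None = None,
                 config: RunConfig | None = None):
        if not chains:
            raise ValueError("fit requires at least one chain")
        self.chains = chains
        self.model = model
        self.config = config

    @property
    def warmup(self) -> int:
        return self.chains[0].warmup

    @property
    def param_names(self) -> list:
        return list(self.chains[0].param_names)

    @property
    def algorithm(self) -> str:
        return self.chains[0].algorithm

    def posterior_array(self, include_warmup: bool = False, constrained: bool = True) -> np.ndarray:
        """Draws as (chains, iterations, params)."""
        lo = 0 if include_warmup else self.warmup
        stack = np.stack([c.draws[lo:] for c in self.chains])
        if constrained and self.model is not None:
            flat = stack.reshape(-1, stack.shape[-1])
            flat = _constrain_draws(flat, self.model.specs)
            stack = flat.reshape(stack.shape)
        return stack

    def lp_array(self, include_warmup: bool = False) -> np.ndarray:
        lo = 0 if include_warmup else self.warmup
        return np.stack([c.lp[lo:] for c in self.chains])

    def draws_constrained(self, include_warmup: bool = False) -> np.ndarray:
        """Merged-chain draws on the constrained scale, one row per draw."""
        arr = self.posterior_array(include_warmup=include_warmup)
        return arr.reshape(-1, arr.shape[-1])


def _chain_rng(seed: int, chain_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(chain_id)]))


def _init_point(model: ModelPosterior, rng: np.random.Generator,
                init: np.ndarray | None) -> np.ndarray:
    if init is not None:
        q0 = np.asarray(init, dtype=float)
        if q0.size != model.dim:
            raise ValueError("init vector has wrong dimension")
        return q0
    return rng.uniform(-2.0, 2.0, size=model.dim)


def _run_nuts_chain(model: ModelPosterior, chain_id: int, cfg: RunConfig,
                    init: np.ndarray | None, fixed_metric: Metric | None) -> ChainOutput:
    rng = _chain_rng(cfg.seed, chain_id)
    q = _init_point(model, rng, init)
    if not math.isfinite(model.logp(q)):
        raise ValueError(f"non-finite log density at the initial point of chain {chain_id}")
    t0 = time.perf_counter()
    metric_kind = cfg.metric if cfg.metric != "auto" else "diag"
    adapter = WarmupAdapter(
        model, cfg.warmup, metric_kind=metric_kind, delta=cfg.adapt_delta,
        fixed_metric=fixed_metric, fixed_stepsize=cfg.stepsize,
    )
    adapter.start(q, rng)

    dim = model.dim
    draws = np.empty((cfg.iter, dim))
    lp = np.empty(cfg.iter)
    sp = {c: np.empty(cfg.iter) for c in NUTS_COLUMNS}
    for it in range(cfg.iter):
        if it == cfg.warmup:
            adapter.finish()
        q, info = nuts_transition(q, adapter.eps, adapter.metric, model,
                                  cfg.max_treedepth, rng)
        draws[it] = q
        lp[it] = info.logp
        sp["accept_stat__"][it] = info.accept_stat
        sp["stepsize__"][it] = info.stepsize
        sp["treedepth__"][it] = info.treedepth
        sp["n_leapfrog__"][it] = info.n_leapfrog
        sp["divergent__"][it] = info.divergent
        sp["energy__"][it] = info.energy
        if it < cfg.warmup:
            adapter.update(it, q, info.accept_stat, rng)
    inv_mass = adapter.metric.inv_mass
    return ChainOutput(
        chain_id=chain_id, draws=draws, sampler_params=sp, lp=lp,
        warmup=cfg.warmup, param_names=model.param_names, algorithm="nuts",
        stepsize=adapter.eps, metric_kind=adapter.metric.kind,
        inv_mass=None if inv_mass is None else np.array(inv_mass),
        seed=cfg.seed, wall_time=time.perf_counter() - t0,
    )


def _run_rwm_chain(model: ModelPosterior, chain_id: int, cfg: RunConfig,
                   init: np.ndarray | None, proposal_cov: np.ndarray | None,
                   scale: float | None) -> ChainOutput:
    rng = _chain_rng(cfg.seed, chain_id)
    q = _init_point(model, rng, init)
    logp = model.logp(q)
    if not math.isfinite(logp):
        raise ValueError(f"non-finite log density at the initial point of chain {chain_id}")
    t0 = time.perf_counter()
    cov = np.eye(model.dim) if proposal_cov is None else np.asarray(proposal_cov, float)
    L = np.linalg.cholesky(cov)
    s = default_scale(model.dim) if scale is None else float(scale)
    draws = np.empty((cfg.iter, model.dim))
    lp = np.empty(cfg.iter)
    sp = {c: np.empty(cfg.iter) for c in RWM_COLUMNS}
    for it in range(cfg.iter):
        lp_old = logp
        q, logp, acc = rwm_transition(q, logp, L, s, model, rng)
        draws[it] = q
        lp[it] = logp
        sp["accepted__"][it] = acc
        sp["accept_stat__"][it] = acc if acc else min(1.0, math.exp(min(0.0, logp - lp_old)))
    return ChainOutput(
        chain_id=chain_id, draws=draws, sampler_params=sp, lp=lp,
        warmup=cfg.warmup, param_names=model.param_names, algorithm="rwm",
        seed=cfg.seed, wall_time=time.perf_counter() - t0,
    )


def sample(
    model: ModelPosterior,
    chains: int = 3,
    iter: int = 2000,
    warmup: int = 1000,
    seed: int = 1,
    init: list | None = None,
    algorithm: str = "nuts",
    adapt_delta: float = 0.8,
    max_treedepth: int = 12,
    metric: str = "diag",
    metric_matrix: np.ndarray | None = None,
    stepsize: float | None = None,
    proposal_cov: np.ndarray | None = None,
    rwm_scale: float | None = None,
    parallel: bool = False,
) -> SamplerFit:
    """Run NUTS or RWM chains.

    ``init`` is a list of per-chain unconstrained vectors (or None for
    uniform(-2, 2) starts).  ``metric_matrix`` supplies a dense inverse
    mass matrix (e.g. a mode-based covariance) and bypasses metric
    adaptation.  The (seed, chain index) pair fully determines each chain.
    """
    cfg = RunConfig(model=model.name, algorithm=algorithm, chains=chains, iter=iter,
                    warmup=warmup, seed=seed, adapt_delta=adapt_delta,
                    max_treedepth=max_treedepth, metric=metric, stepsize=stepsize,
                    parallel=parallel)
    if init is not None and len(init) != chains:
        raise ValueError("need one init vector per chain")
    inits = init if init is not None else [None] * chains

    fixed_metric = None
    if metric_matrix is not None:
        fixed_metric = Metric.dense(np.asarray(metric_matrix, dtype=float))
        cfg.metric = "dense"

    def run_one(cid: int) -> ChainOutput:
        import copy

        m = copy.deepcopy(model)  # isolate any per-chain mutable state (warm starts)
        if algorithm == "nuts":
            return _run_nuts_chain(m, cid, cfg, inits[cid], fixed_metric)
        if algorithm == "rwm":
            return _run_rwm_chain(m, cid, cfg, inits[cid], proposal_cov, rwm_scale)
        raise ValueError(f"unknown algorithm {algorithm!r}")

    if parallel and chains > 1:
        # thread-backed: chains share no mutable state (models are copied),
        # and the seed contract makes scheduling irrelevant to the output
        from joblib import Parallel, delayed

        outs = Parallel(n_jobs=min(chains, 4), prefer="threads")(
            delayed(run_one)(cid) for cid in range(chains)
        )
    else:
        outs = [run_one(cid) for cid in range(chains)]
    return SamplerFit(list(outs), model=model, config=cfg)


def rwm_chain(model: ModelPosterior, iter: int = 2000, warmup: int = 1000,
              proposal_cov: np.ndarray | None = None, scale: float | None = None,
              seed: int = 1, chain_id: int = 0, init: np.ndarray | None = None) -> ChainOutput:
    """Single random-walk Metropolis chain (mode-based proposal by default).

    With ``proposal_cov=None`` the proposal covariance is the mode-based
    (inverse-Hessian) covariance when the mode finder converges, else the
    identity — the historical mode-centred workflow.
    """
    if proposal_cov is None:
        mr = find_mode(model)
        proposal_cov = mr.covariance if mr.converged else None
    cfg = RunConfig(model=model.name, algorithm="rwm", chains=1, iter=iter,
                    warmup=warmup, seed=seed)
    return _run_rwm_chain(model, chain_id, cfg, init, proposal_cov, scale)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_samples(fit: SamplerFit, include_warmup: bool = False,
                    include_lp: bool = False) -> pd.DataFrame:
    """Merged-chain draws on the constrained scale as a table."""
    arr = fit.posterior_array(include_warmup=include_warmup)
    flat = arr.reshape(-1, arr.shape[-1])
    df = pd.DataFrame(flat, columns=fit.param_names)
    if include_lp:
        df["lp__"] = fit.lp_array(include_warmup=include_warmup).reshape(-1)
    return df


def extract_sampler_params(fit: SamplerFit, include_warmup: bool = True) -> pd.DataFrame:
    """Per-iteration sampler metadata across chains."""
    frames = []
    for c in fit.chains:
        lo = 0 if include_warmup else c.warmup
        cols = NUTS_COLUMNS if c.algorithm == "nuts" else RWM_COLUMNS
        d = {"chain": np.full(c.n_iter - lo, c.chain_id),
             "iteration": np.arange(lo, c.n_iter)}
        for col in cols:
            d[col] = c.sampler_params[col][lo:]
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_chain_csv(chain: ChainOutput, path) -> None:
    """Write one chain in the comment-headed CSV dialect."""
    path = Path(path)
    cols = NUTS_COLUMNS if chain.algorithm == "nuts" else RWM_COLUMNS
    with path.open("w") as fh:
        fh.write("# lapnuts chain\n")
        fh.write(f"# algorithm: {chain.algorithm}\n")
        fh.write(f"# chain: {chain.chain_id}\n")
        fh.write(f"# iter: {chain.n_iter}\n")
        fh.write(f"# warmup: {chain.warmup}\n")
        fh.write(f"# seed: {chain.seed}\n")
        fh.write(f"# stepsize: {float(chain.stepsize)!r}\n")
        fh.write(f"# metric_kind: {chain.metric_kind}\n")
        if chain.inv_mass is not None and chain.inv_mass.ndim == 1:
            fh.write("# inv_mass: " + " ".join(repr(float(v)) for v in chain.inv_mass) + "\n")
        header = ["lp__"] + cols + list(chain.param_names)
        fh.write(",".join(header) + "\n")
        for it in range(chain.n_iter):
            row = [chain.lp[it]] + [chain.sampler_params[c][it] for c in cols] \
                + list(chain.draws[it])
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_chain_csv(path) -> ChainOutput:
    """Read a chain written by :func:`write_chain_csv` (lossless round trip)."""
    path = Path(path)
    meta: dict = {}
    header = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            if header is None:
                header = parts
                continue
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    if header is None or not rows:
        raise ValueError(f"{path}: no chain data found")
    data = np.array(rows)
    if data.shape[1] != len(header):
        raise ValueError(f"{path}: column count mismatch with header")
    algorithm = meta.get("algorithm", "nuts")
    cols = NUTS_COLUMNS if algorithm == "nuts" else RWM_COLUMNS
    n_meta = 1 + len(cols)
    param_names = header[n_meta:]
    sp = {c: data[:, 1 + i] for i, c in enumerate(cols)}
    inv_mass = None
    if "inv_mass" in meta:
        inv_mass = np.array([float(v) for v in meta["inv_mass"].split()])
    step = meta.get("stepsize", "nan")
    return ChainOutput(
        chain_id=int(meta.get("chain", 0)),
        draws=data[:, n_meta:],
        sampler_params=sp,
        lp=data[:, 0],
        warmup=int(meta.get("warmup", 0)),
        param_names=param_names,
        algorithm=algorithm,
        stepsize=float(step),
        metric_kind=meta.get("metric_kind", "diag"),
        inv_mass=inv_mass,
        seed=int(meta.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# efficiency harness
# ---------------------------------------------------------------------------

def benchmark(model: ModelPosterior, replicates: int = 30, seed: int = 1,
              iter: int = 2000, warmup: int = 1000, **kwargs) -> pd.DataFrame:
    """Replicate single-chain runs and report min-ESS, runtime and their ratio.

    Each replicate starts from its own diffuse initial point.  The
    returned table has one row per replicate; medians and interquartile
    ranges are attached as ``df.attrs['summary']``.  Wall times are
    hardware-dependent and are never part of any acceptance check.
    """
    from .diagnostics import ess

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for r in range(replicates):
        fit = sample(model, chains=1, iter=iter, warmup=warmup,
                     seed=seed + r, **kwargs)
        arr = fit.posterior_array()
        min_ess = float(np.nanmin(ess(arr)))
        runtime = fit.chains[0].wall_time
        rows.append({"replicate": r, "min_ess": min_ess, "runtime": runtime,
                     "ess_per_sec": min_ess / runtime})
    df = pd.DataFrame(rows)
    q = df[["min_ess", "runtime", "ess_per_sec"]].quantile([0.25, 0.5, 0.75])
    df.attrs["summary"] = q.rename(index={0.25: "q25", 0.5: "median", 0.75: "q75"})
    return df
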