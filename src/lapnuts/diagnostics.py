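"""Convergence diagnostics and the Laplace-approximation audit.

Split potential-scale-reduction (R-hat) and effective sample size follow
the standard split-chain construction: each chain is halved, the
between/within variance ratio gives R-hat, and ESS combines per-chain FFT
autocorrelations with Geyer's initial monotone positive sequence.

The audit (``compare_versions``) operationalizes the visual QQ comparison
of the fixed-effect posteriors under full MCMC integration versus Laplace
marginalization: both versions are thinned to comparable effective sample
sizes (different mixing rates otherwise make the comparison misleading),
then each fixed effect is compared by a two-sample Kolmogorov-Smirnov
test, Bonferroni-corrected across fixed effects at family level 0.01.
The paper-style figure flags differences visually; the KS flag is this
package's numeric criterion for the same question — a flagged difference
suggests the Laplace approximation's assumptions are not met.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .laplace import LaplaceConfig, make_marginal_model

__all__ = ["MonitorRow", "ComparisonReport", "split_rhat", "ess", "monitor",
           "count_divergences", "thin_to_match_ess", "qq_compare",
           "compare_versions"]

logger = logging.getLogger(__name__)


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(chains, iters) -> (2*chains, iters//2), dropping a trailing odd draw."""
    m, n = draws.shape
    half = n // 2
    return np.concatenate([draws[:, :half], draws[:, n - half:]], axis=0)


def _rhat_1d(draws: np.ndarray) -> float:
    sc = _split_chains(draws)
    m, n = sc.shape
    if n < 2:
        return math.nan
    W = sc.var(axis=1, ddof=1).mean()
    if W <= 0 or not np.isfinite(W):
        logger.warning("zero within-chain variance; R-hat undefined")
        return math.nan
    B_over_n = sc.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return math.sqrt(var_plus / W)


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Autocovariance (biased, lag 0..n-1) of one centered chain via FFT."""
    n = x.size
    xc = x - x.mean()
    size = 1
    while size < 2 * n:
        size <<= 1
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real / n
    return acov


def _ess_1d(draws: np.ndarray) -> float:
    sc = _split_chains(draws)
    m, n = sc.shape
    if n < 4:
        return math.nan
    acov = np.array([_autocorr_fft(c) for c in sc])
    chain_var = acov[:, 0] * n / (n - 1.0)
    W = chain_var.mean()
    mean_var = acov.mean(axis=0)
    var_plus = W * (n - 1.0) / n
    if m > 1:
        var_plus += sc.mean(axis=1).var(ddof=1)
    if var_plus <= 0 or not np.isfinite(var_plus):
        logger.warning("zero variance; ESS undefined")
        return math.nan
    # combined autocorrelation, then Geyer initial monotone positive sums
    rho = 1.0 - (W - mean_var) / var_plus
    rho[0] = 1.0
    max_pairs = (n - 2) // 2
    paired = []
    prev = math.inf
    for k in range(max_pairs + 1):
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        g = min(g, prev)  # enforce monotone non-increasing
        paired.append(g)
        prev = g
    # strongly antithetic chains can drive tau to zero or below; the floor
    # lets n_eff exceed the nominal draw count up to the 2x cap
    tau = -1.0 + 2.0 * sum(paired) if paired else 0.0
    tau = max(tau, 1.0 / math.log10(n * m + 10.0))
    n_eff = m * n / tau
    return float(min(n_eff, 2.0 * m * n))


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split R-hat per parameter for draws shaped (chains, iters[, params])."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if draws.shape[1] < 2:
        raise ValueError("need at least 2 iterations per chain")
    return np.array([_rhat_1d(draws[:, :, j]) for j in range(draws.shape[2])])


def ess(draws: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter, (chains, iters[, params]).

    Capped at twice the total draw count; antithetic chains may legitimately
    exceed the nominal size.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if draws.shape[1] < 8:
        raise ValueError("need at least 8 iterations per chain for ESS")
    return np.array([_ess_1d(draws[:, :, j]) for j in range(draws.shape[2])])


@dataclass
class MonitorRow:
    name: str
    mean: float
    sd: float
    q2_5: float
    q25: float
    q50: float
    q75: float
    q97_5: float
    n_eff: float
    rhat: float


def monitor(fit) -> pd.DataFrame:
    """Posterior summary table: one row per parameter plus lp__."""
    arr = fit.posterior_array()            # chains x iters x params
    lp = fit.lp_array()[:, :, None]
    full = np.concatenate([arr, lp], axis=2)
    names = fit.param_names + ["lp__"]
    r = split_rhat(full)
    e = ess(full)
    flat = full.reshape(-1, full.shape[-1])
    qs = np.percentile(flat, [2.5, 25, 50, 75, 97.5], axis=0)
    df = pd.DataFrame({
        "mean": flat.mean(axis=0),
        "sd": flat.std(axis=0, ddof=1),
        "2.5%": qs[0], "25%": qs[1], "50%": qs[2], "75%": qs[3], "97.5%": qs[4],
        "n_eff": e, "rhat": r,
    }, index=names)
    return df


def count_divergences(fit) -> int:
    """Total post-warmup divergent transitions across chains."""
    total = 0
    for c in fit.chains:
        total += int(np.asarray(c.sampler_params["divergent__"][c.warmup:]).sum())
    return total


def thin_to_match_ess(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Thin two draw sets to comparable effective sample sizes.

    ``a``/``b`` are (chains, iters, params).  Each is thinned by the
    stride n / min-ESS implied by its own worst-mixing parameter (rounded
    to the nearest integer, so ESS-estimator noise on well-mixed chains
    does not halve them), then both merged sets are truncated to the
    common length.  Returns flat (draws, params) arrays.
    """
    out = []
    for x in (a, b):
        x = np.asarray(x, dtype=float)
        n = x.shape[0] * x.shape[1]
        e = ess(x)
        if np.any(~np.isfinite(e)):
            raise ValueError("ESS undefined for at least one parameter; cannot thin")
        stride = max(1, round(n / float(np.min(e))))
        out.append(x[:, ::stride, :].reshape(-1, x.shape[-1]))
    n_common = min(out[0].shape[0], out[1].shape[0])
    return out[0][:n_common], out[1][:n_common]


def qq_compare(a: np.ndarray, b: np.ndarray) -> dict:
    """Sorted-pair QQ comparison plus a two-sample KS test.

    Requires equal lengths (thin first).  ``max_abs_qq_deviation`` is the
    largest vertical distance of the QQ points from the 1:1 line.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    sa, sb = np.sort(a), np.sort(b)
    ks = stats.ks_2samp(a, b, method="asymp")
    return {
        "qq_points": np.column_stack([sa, sb]),
        "max_abs_qq_deviation": float(np.max(np.abs(sa - sb))),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


@dataclass
class ComparisonReport:
    """Per-fixed-effect discrepancy between full and marginalized runs."""

    records: dict = field(default_factory=dict)   # name -> qq_compare dict + thinning info
    alpha: float = 0.01
    flagged: list = field(default_factory=list)
    overall: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = {name: {k: rec[k] for k in ("max_abs_qq_deviation", "ks_stat", "ks_p",
                                           "matched_ess")}
                for name, rec in self.records.items()}
        df = pd.DataFrame(rows).T
        df["flagged"] = [n in self.flagged for n in df.index]
        return df


def compare_versions(joint_model, cfg: LaplaceConfig | None = None,
                     run_settings: dict | None = None,
                     run_settings_laplace: dict | None = None,
                     alpha: float = 0.01) -> ComparisonReport:
    """Audit the Laplace approximation by running both integration versions.

    Runs NUTS on the joint model (full MCMC integration of the random
    effects) and on the Laplace-marginalized model, ESS-matches the two
    fixed-effect posteriors, and KS-compares each fixed effect with a
    Bonferroni family level ``alpha``.  ``overall`` is True when any fixed
    effect differs detectably — evidence the Laplace assumptions are not
    met for this model and data.

    ``run_settings_laplace`` overrides the marginalized run's settings;
    the two versions have very different per-iteration costs (the Laplace
    version pays an inner optimization per leapfrog step but samples a far
    smaller space), so matching their effective sample sizes efficiently
    usually means different chain lengths — the ESS-matched thinning below
    is what makes the comparison fair.
    """
    from .sampling import sample

    settings = dict(chains=2, iter=1000, warmup=500, seed=1)
    if run_settings:
        settings.update(run_settings)
    settings_lap = dict(settings)
    if run_settings_laplace:
        settings_lap.update(run_settings_laplace)
    cfg = cfg or LaplaceConfig()
    try:
        fit_full = sample(joint_model, **settings)
    except Exception as exc:
        raise RuntimeError(f"full-integration run failed: {exc}") from exc
    try:
        marginal = make_marginal_model(joint_model, cfg)
        fit_lap = sample(marginal, **settings_lap)
    except Exception as exc:
        raise RuntimeError(f"laplace-integration run failed: {exc}") from exc

    fidx = joint_model.fixed_index()
    names = [joint_model.param_names[i] for i in fidx]
    full_arr = fit_full.posterior_array()[:, :, fidx]
    lap_arr = fit_lap.posterior_array()
    a, b = thin_to_match_ess(full_arr, lap_arr)
    matched = a.shape[0]

    report = ComparisonReport(alpha=alpha)
    threshold = alpha / max(len(names), 1)
    for j, name in enumerate(names):
        rec = qq_compare(a[:, j], b[:, j])
        rec["thin_full"] = full_arr.shape[0] * full_arr.shape[1] // max(matched, 1)
        rec["thin_laplace"] = lap_arr.shape[0] * lap_arr.shape[1] // max(matched, 1)
        rec["matched_ess"] = matched
        report.records[name] = rec
        if rec["ks_p"] < threshold:
            report.flagged.append(name)
    report.overall = bool(report.flagged)
    return report
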