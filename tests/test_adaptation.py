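"""Dual averaging, warmup windowing, metric estimation."""

import math

import numpy as np
import pytest

import lapnuts as ln
from lapnuts.adaptation import (build_schedule, da_init, da_update, estimate_metric,
                                find_reasonable_stepsize)
from lapnuts.metric import Metric


# -- dual averaging --------------------------------------------------------

def test_da_on_target_keeps_stepsize():
    s = da_init(1.0, delta=0.8)
    for _ in range(50):
        s = da_update(s, 0.8)
    # H_bar stays 0, so log_eps stays at mu
    assert s.log_eps == pytest.approx(s.mu, abs=1e-12)


def test_da_zero_acceptance_shrinks_stepsize():
    # H_bar > 0 accumulates, so log_eps decreases monotonically from the
    # first update onward (the very first step jumps to the mu anchor)
    s = da_update(da_init(1.0, delta=0.8), 0.0)
    prev = s.log_eps
    for _ in range(20):
        s = da_update(s, 0.0)
        assert s.log_eps < prev
        prev = s.log_eps


def test_da_hand_computed_first_step():
    # t=1, gamma=0.05, t0=10, delta=0.8, accept=0.6, mu=log(1)=0:
    # H_bar = 0.2/11, log_eps = -sqrt(1)/0.05 * H_bar = -0.363636...
    s = da_init(0.1, delta=0.8)
    s = type(s)(mu=0.0, log_eps=0.0, delta=0.8)
    s = da_update(s, 0.6)
    assert s.H_bar == pytest.approx(0.2 / 11.0, abs=1e-12)
    assert s.log_eps == pytest.approx(-(0.2 / 11.0) / 0.05, abs=1e-10)


def test_da_rejects_bad_delta():
    with pytest.raises(ValueError):
        da_init(1.0, delta=1.5)


# -- schedule --------------------------------------------------------------

def test_schedule_stan_windowing():
    sched = build_schedule(1000, 75, 50, 25)
    assert sched.window_ends == [100, 150, 250, 450, 950]


def test_schedule_short_warmup_degrades_to_single_window():
    sched = build_schedule(120, 75, 50, 25)
    assert len(sched.window_ends) == 1
    assert sched.window_ends[-1] == 120 - sched.term_buffer
    assert sched.init_buffer + sched.base_window + sched.term_buffer == 120


def test_schedule_rejects_nonpositive_warmup():
    with pytest.raises(ValueError):
        build_schedule(0)


def test_schedule_windows_tile_and_double():
    sched = build_schedule(2000, 75, 50, 25)
    starts = [sched.init_buffer] + sched.window_ends[:-1]
    sizes = [e - s for s, e in zip(starts, sched.window_ends)]
    # every window at least base_window; doubling until the absorbed tail
    assert all(sz >= sched.base_window for sz in sizes)
    for a, b in zip(sizes[:-2], sizes[1:-1]):
        assert b == 2 * a
    assert sched.window_ends[-1] == 2000 - sched.term_buffer


# -- metric estimation -----------------------------------------------------

def test_estimate_metric_regularizer_floor():
    draws = np.ones((40, 3))  # zero sample variance
    met = estimate_metric(draws, "diag")
    expected = (1.0 - 40 / 45.0) * 1e-3
    np.testing.assert_allclose(met.inv_mass, expected, rtol=1e-12)


def test_estimate_metric_diag_converges_to_variance(rng):
    sig2 = np.array([0.5, 2.0, 9.0])
    draws = rng.normal(0.0, np.sqrt(sig2), size=(10_000, 3))
    met = estimate_metric(draws, "diag")
    np.testing.assert_allclose(met.inv_mass, sig2, rtol=0.05)


def test_estimate_metric_dense_formula(rng):
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    draws = rng.multivariate_normal(np.zeros(2), cov, size=500)
    met = estimate_metric(draws, "dense")
    n = 500
    expected = n / (n + 5) * np.cov(draws, rowvar=False) \
        + 5 / (n + 5) * 1e-3 * np.eye(2)
    np.testing.assert_allclose(met.inv_mass, expected, rtol=1e-10)


def test_estimate_metric_too_few_draws_keeps_previous():
    prev = Metric.diag(np.array([2.0]))
    met = estimate_metric(np.zeros((3, 1)), "diag", prev=prev)
    assert met is prev
    with pytest.raises(ValueError):
        estimate_metric(np.zeros((3, 1)), "diag", prev=None)


# -- metric object ---------------------------------------------------------

def test_metric_momentum_covariance(rng):
    # p ~ N(0, M) with M the inverse of inv_mass
    inv_mass = np.array([[2.0, 0.8], [0.8, 1.0]])
    met = Metric.dense(inv_mass)
    ps = np.array([met.sample_momentum(rng) for _ in range(20_000)])
    np.testing.assert_allclose(np.cov(ps, rowvar=False), np.linalg.inv(inv_mass),
                               atol=0.06)


def test_metric_rejects_invalid():
    with pytest.raises(ValueError):
        Metric.diag(np.array([1.0, -1.0]))
    with pytest.raises(np.linalg.LinAlgError):
        Metric.dense(np.array([[1.0, 2.0], [2.0, 1.0]]))


# -- step size search ------------------------------------------------------

def test_find_reasonable_stepsize_std_normal(std_normal_1d, rng):
    eps = find_reasonable_stepsize(std_normal_1d, np.zeros(1), Metric.unit(1), rng)
    assert 0.5 <= eps <= 4.0


def test_find_reasonable_stepsize_scales_with_target(rng):
    tiny = ln.mvn_model([0.0], [[1e-6]])
    eps_tiny = np.median([
        find_reasonable_stepsize(tiny, np.zeros(1), Metric.unit(1),
                                 np.random.default_rng(s)) for s in range(10)
    ])
    big = ln.mvn_model([0.0], [[1.0]])
    eps_big = np.median([
        find_reasonable_stepsize(big, np.zeros(1), Metric.unit(1),
                                 np.random.default_rng(s)) for s in range(10)
    ])
    assert eps_big / eps_tiny > 100  # ~1e3 scale separation


def test_preconditioning_restores_unit_scale(rng):
    tiny = ln.mvn_model([0.0], [[1e-6]])
    eps_pre = find_reasonable_stepsize(tiny, np.zeros(1), Metric.diag(np.array([1e-6])), rng)
    big = ln.mvn_model([0.0], [[1.0]])
    eps_unit = find_reasonable_stepsize(big, np.zeros(1), Metric.unit(1), rng)
    assert 0.5 <= eps_pre / eps_unit <= 2.0


# -- end-to-end adaptation properties --------------------------------------

def test_raising_adapt_delta_shrinks_stepsize():
    """adapt_delta 0.8 -> 0.9 strictly reduces the adapted step size in
    distribution (median over seeds) — the recommended response to
    divergent transitions."""
    m = ln.mvn_model(np.zeros(3), np.eye(3))
    eps = {}
    for delta in (0.8, 0.9):
        vals = []
        for seed in range(10):
            fit = ln.sample(m, chains=1, iter=450, warmup=400, seed=seed,
                            adapt_delta=delta)
            vals.append(fit.chains[0].stepsize)
        eps[delta] = np.median(vals)
    assert eps[0.9] < eps[0.8]


def test_diagonal_metric_adapts_to_anisotropy():
    m = ln.mvn_model(np.zeros(2), np.diag([1.0, 100.0]))
    fit = ln.sample(m, chains=1, iter=1100, warmup=1000, seed=3)
    inv_mass = fit.chains[0].inv_mass
    assert 0.5 <= inv_mass[0] <= 2.0
    assert 50.0 <= inv_mass[1] <= 200.0


def test_dense_user_metric_improves_ess_per_gradient():
    """Supplying the true covariance as a dense metric raises min-ESS per
    gradient evaluation on a strongly correlated Gaussian (median over
    seeds)."""
    from lapnuts.diagnostics import ess

    rho = 0.95
    cov = np.array([[1.0, rho], [rho, 1.0]])
    m = ln.mvn_model(np.zeros(2), cov)

    def eff(seed, metric_matrix, metric):
        fit = ln.sample(m, chains=1, iter=600, warmup=300, seed=seed,
                        metric=metric, metric_matrix=metric_matrix)
        sp = ln.extract_sampler_params(fit, include_warmup=False)
        return float(np.min(ess(fit.posterior_array()))) / sp["n_leapfrog__"].sum()

    unit = np.median([eff(s, None, "unit") for s in range(10)])
    dense = np.median([eff(s, cov, "dense") for s in range(10)])
    assert dense > unit
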