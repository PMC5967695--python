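"""Case-study models: generators, likelihoods, oracles."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.special import expit

import lapnuts as ln


# -- analytic targets ------------------------------------------------------

def test_mvn_logp_and_gradient_at_mean():
    cov = np.array([[2.0, 0.5], [0.5, 1.0]])
    m = ln.mvn_model(np.array([1.0, -1.0]), cov)
    lp, g = m.logp_grad(np.array([1.0, -1.0]))
    expected = -0.5 * (2 * math.log(2 * math.pi) + math.log(np.linalg.det(cov)))
    assert lp == pytest.approx(expected, abs=1e-12)
    np.testing.assert_allclose(g, 0.0, atol=1e-12)


def test_mvn_rejects_non_spd():
    with pytest.raises(ValueError):
        ln.mvn_model(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
    with pytest.raises(ValueError):
        ln.funnel_model(1)


def test_funnel_parameterizations_same_joint_law():
    """Centered and non-centered funnels define the same joint law of
    (v, x): moments of long RWM runs agree within joint 3 MCSE."""
    from lapnuts.diagnostics import ess

    mc = ln.funnel_model(2, centered=True)
    mn = ln.funnel_model(2, centered=False)
    fit_c = ln.sample(mc, chains=2, iter=40_000, warmup=2000, seed=1,
                      algorithm="rwm", proposal_cov=np.diag([9.0, 3.0]))
    fit_n = ln.sample(mn, chains=2, iter=40_000, warmup=2000, seed=2,
                      algorithm="rwm", proposal_cov=np.diag([9.0, 1.0]))
    vc = fit_c.posterior_array()[:, :, 0]
    vn = fit_n.posterior_array()[:, :, 0]
    # compare the funnel depth v (x is scale-mixed and heavy-tailed)
    se = math.sqrt(vc.var() / float(ess(vc)[0]) + vn.var() / float(ess(vn)[0]))
    assert abs(vc.mean() - vn.mean()) < 3 * se
    # and against the exact marginal v ~ N(0, 9)
    assert abs(vc.mean()) < 3 * math.sqrt(vc.var() / float(ess(vc)[0]))


# -- wildflower ------------------------------------------------------------

def test_gen_wildflower_neutral_parameters_give_half_probability():
    data = ln.gen_wildflower(n_plants=60, n_years=5, trials_per_obs=10,
                             params=dict(beta0=0.0, beta_size=0.0, sigma_year=0.0,
                                         sigma_plant_int=0.0, sigma_plant_slope=0.0),
                             seed=0)
    # every success probability is exactly logistic(0) = 0.5
    rate = data.successes.sum() / data.trials.sum()
    assert rate == pytest.approx(0.5, abs=0.02)


def test_gen_wildflower_reproducible_and_validated():
    a = ln.gen_wildflower(seed=42)
    b = ln.gen_wildflower(seed=42)
    np.testing.assert_array_equal(a.successes, b.successes)
    np.testing.assert_array_equal(a.size, b.size)
    with pytest.raises(ValueError):
        ln.gen_wildflower(n_plants=0)
    with pytest.raises(ValueError):
        ln.gen_wildflower(params=dict(sigma_year=-1.0))


def test_gen_wildflower_year_variance_dominates_when_sigma_year_huge():
    data = ln.gen_wildflower(n_plants=300, n_years=8, trials_per_obs=30,
                             params=dict(sigma_year=4.0, sigma_plant_int=0.1,
                                         sigma_plant_slope=0.0, beta_size=0.0),
                             seed=3)
    p_hat = np.clip(data.successes / data.trials, 1e-3, 1 - 1e-3)
    logit = np.log(p_hat / (1 - p_hat))
    year_means = np.array([logit[data.year == j].mean() for j in range(8)])
    within = np.mean([logit[data.year == j].var() for j in range(8)])
    assert year_means.var() > 3 * within


def test_wildflower_parameter_count():
    data = ln.gen_wildflower(n_plants=13, n_years=4, seed=0)
    m = ln.wildflower_model(data)
    assert m.dim == 5 + 4 + 2 * 13
    assert sum(s.role == "random" for s in m.specs) == 4 + 2 * 13


def test_wildflower_logp_hand_computed_toy():
    """Two observations, all REs at zero: the density is the binomial
    log-likelihood at p = logistic(beta0) plus the prior terms."""
    data = ln.WildflowerData(
        n_plants=1, n_years=2, plant=np.array([0, 0]), year=np.array([0, 1]),
        trials=np.array([3, 2]), successes=np.array([2, 1]), size=np.zeros(2),
    )
    m = ln.wildflower_model(data)
    beta0 = 0.4
    q = np.zeros(m.dim)
    q[0] = beta0
    p = expit(beta0)
    binom = (math.log(math.comb(3, 2)) + 2 * math.log(p) + 1 * math.log(1 - p)
             + math.log(math.comb(2, 1)) + math.log(p) + math.log(1 - p))
    # priors: N(0,25) on beta0 and beta_size(=0); half-N jacobian terms at
    # log sigma = 0: -1/50 + 0 each; raw REs all zero contribute 0
    prior = -0.5 * beta0**2 / 25.0 + 3 * (-1.0 / 50.0)
    assert m.logp(q) == pytest.approx(binom + prior, abs=1e-12)


# -- swallows --------------------------------------------------------------

def test_gen_swallows_reproducible():
    a = ln.gen_swallows(dict(n_broods=10, n_years=2, n_occasions=6), seed=9)
    b = ln.gen_swallows(dict(n_broods=10, n_years=2, n_occasions=6), seed=9)
    np.testing.assert_array_equal(a.histories, b.histories)
    with pytest.raises(ValueError):
        ln.gen_swallows(dict(n_broods=0))


def test_gen_swallows_survival_detection_limits():
    data = ln.gen_swallows(dict(n_broods=10, n_years=2, n_occasions=6,
                                b0=30.0, b_env=0.0, b_size=0.0, a0=30.0, a_eff=0.0,
                                sigma_brood_phi=0.0, sigma_brood_p=0.0,
                                sigma_year_phi=0.0), seed=1)
    # everyone survives and is always detected after first capture
    for i in range(data.n_individuals):
        assert np.all(data.histories[i, data.first[i]:] == 1)


def test_gen_swallows_shapes_and_first_before_last():
    data = ln.gen_swallows(dict(n_broods=12, n_years=3, n_occasions=5), seed=2)
    assert data.histories.shape == (24, 5)
    assert np.all(data.first <= data.last)
    assert np.all(data.histories[np.arange(24), data.first] == 1)


def test_swallows_fixture_dimensions():
    m = ln.get_model("swallows")
    assert len(m.fixed_effect_names) == 5
    assert sum(s.role == "random" for s in m.specs) == 172


def test_swallows_chi_recursion_hand_single_history():
    """One individual captured at occasion 0 and never again, constant
    phi = p = 0.5 over 3 occasions: P(history) = chi_0 where
    chi_t = (1-phi) + phi (1-p) chi_{t+1}."""
    data = ln.SwallowsData(
        n_individuals=1, n_occasions=3, n_broods=1, n_years=1,
        histories=np.array([[1, 0, 0]]), first=np.array([0]), last=np.array([0]),
        size=np.zeros(1), env=np.zeros(2), effort=np.zeros(3),
        brood=np.array([0]), year=np.array([0]),
    )
    m = ln.swallows_model(data)
    q = np.zeros(m.dim)  # all logits 0 -> phi = p = 0.5
    chi2 = 1.0
    chi1 = 0.5 + 0.5 * 0.5 * chi2
    chi0 = 0.5 + 0.5 * 0.5 * chi1
    prior = 3 * (-1.0 / 50.0)  # half-normal jacobian terms at log sigma = 0
    assert m.logp(q) == pytest.approx(math.log(chi0) + prior, abs=1e-12)


def _brute_force_cjs_loglik(data, q):
    """Enumerate latent alive-state sequences (oracle for <= 5 occasions)."""
    b0, benv, bsize, a0, aeff = q[:5]
    sbp, sbd, syp = np.exp(q[5:8])
    B, Y, K = data.n_broods, data.n_years, data.n_occasions
    ebphi = sbp * q[8:8 + B]
    ebp = sbd * q[8 + B:8 + 2 * B]
    eyphi = syp * q[8 + 2 * B:8 + 2 * B + Y]
    total = 0.0
    for i in range(data.n_individuals):
        f = data.first[i]
        hist = data.histories[i]
        phis = expit(b0 + benv * data.env + bsize * data.size[i]
                     + ebphi[data.brood[i]] + eyphi[data.year[i]])
        ps = expit(a0 + aeff * data.effort + ebp[data.brood[i]])
        prob = 0.0
        for last_alive in range(f, K):
            pseq = float(np.prod(phis[f:last_alive]))
            if last_alive < K - 1:
                pseq *= 1.0 - phis[last_alive]
            consistent = True
            for t in range(f + 1, K):
                if t <= last_alive:
                    pseq *= ps[t] if hist[t] else 1.0 - ps[t]
                elif hist[t]:
                    consistent = False
            if consistent:
                prob += pseq
        total += math.log(prob)
    return total


def test_swallows_marginal_matches_state_enumeration(rng):
    data = ln.gen_swallows(dict(n_broods=6, n_years=2, n_occasions=5, per_brood=2),
                           seed=13)
    m = ln.swallows_model(data)

    def priors(q):
        lp = -0.5 * float(q[:5] @ q[:5]) / 25.0
        for j in range(3):
            s = math.exp(q[5 + j])
            lp += -0.5 * s * s / 25.0 + q[5 + j]
        return lp - 0.5 * float(q[8:] @ q[8:])

    for _ in range(5):
        q = rng.normal(0, 0.5, m.dim)
        assert m.logp(q) - priors(q) == pytest.approx(
            _brute_force_cjs_loglik(data, q), abs=1e-10)


def test_noncentered_fits_diverge_less_than_centered():
    """Non-centered random effects produce fewer divergences than centered
    at the default target acceptance (summed over seeds) — the reason the
    case models default to the non-centered form."""
    div = {}
    for nc in (False, True):
        tot = 0
        for s in range(3):
            data = ln.gen_wildflower(n_plants=12, n_years=4, trials_per_obs=1,
                                     seed=60 + s)
            m = ln.wildflower_model(data, non_centered=nc)
            fit = ln.sample(m, chains=1, iter=500, warmup=300, seed=s + 1)
            tot += ln.count_divergences(fit)
        div[nc] = tot
    assert div[True] <= div[False]


def test_registry_unknown_model():
    with pytest.raises(KeyError):
        ln.get_model("nope")
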