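"""Leapfrog integrator, U-turn criterion, tree building, one transition."""

import math

import numpy as np
import pytest

import lapnuts as ln
from lapnuts.metric import Metric
from lapnuts.model_api import FunctionModel, ParameterSpec
from lapnuts.nuts_core import (DELTA_MAX, PhasePoint, build_tree, hamiltonian,
                               is_uturn, leapfrog, nuts_transition)


def _std_normal(dim=1):
    return FunctionModel([ParameterSpec(f"q{i}") for i in range(dim)],
                         lambda q: (-0.5 * float(q @ q), -q))


# -- hamiltonian -----------------------------------------------------------

def test_hamiltonian_zero():
    m = FunctionModel([ParameterSpec("q")], lambda q: (0.0, np.zeros(1)))
    pt = PhasePoint.at(np.zeros(1), np.zeros(1), m)
    assert hamiltonian(pt, Metric.unit(1)) == 0.0


def test_hamiltonian_unit_metric():
    m = FunctionModel([ParameterSpec("a"), ParameterSpec("b")],
                      lambda q: (-1.5, np.zeros(2)))
    pt = PhasePoint.at(np.zeros(2), np.ones(2), m)
    assert hamiltonian(pt, Metric.unit(2)) == pytest.approx(2.5)


def test_hamiltonian_mass_diag():
    # mass M = 4: H = -logp + p^2 / (2M)
    m = FunctionModel([ParameterSpec("q")], lambda q: (0.0, np.zeros(1)))
    pt = PhasePoint.at(np.zeros(1), np.array([2.0]), m)
    assert hamiltonian(pt, Metric.from_mass_diag([4.0])) == pytest.approx(0.5)


def test_hamiltonian_infinite_for_nonfinite_density():
    pt = PhasePoint(np.zeros(1), np.zeros(1), -math.inf, np.zeros(1))
    assert hamiltonian(pt, Metric.unit(1)) == math.inf


# -- leapfrog --------------------------------------------------------------

def test_leapfrog_hand_computed_step():
    # 1-d standard normal from (q, p) = (1, 0), eps = 0.1:
    # p_half = -0.05, q' = 1 - 0.005 = 0.995, p' = p_half - 0.05*0.995
    m = _std_normal()
    pt = PhasePoint.at(np.array([1.0]), np.array([0.0]), m)
    out = leapfrog(pt, 0.1, Metric.unit(1), m)
    assert out.q[0] == pytest.approx(0.995, abs=1e-12)
    assert out.p[0] == pytest.approx(-0.09975, abs=1e-12)


def test_leapfrog_backward_recovers_input():
    m = _std_normal(3)
    rng = np.random.default_rng(1)
    pt = PhasePoint.at(rng.normal(size=3), rng.normal(size=3), m)
    fwd = leapfrog(pt, 0.3, Metric.unit(3), m)
    back = leapfrog(PhasePoint(fwd.q, -fwd.p, fwd.logp, fwd.grad), 0.3, Metric.unit(3), m)
    np.testing.assert_allclose(back.q, pt.q, atol=1e-12)
    np.testing.assert_allclose(-back.p, pt.p, atol=1e-12)


def test_leapfrog_zero_step_is_identity():
    m = _std_normal(2)
    pt = PhasePoint.at(np.array([0.4, -1.0]), np.array([0.2, 0.1]), m)
    out = leapfrog(pt, 0.0, Metric.unit(2), m)
    np.testing.assert_array_equal(out.q, pt.q)
    np.testing.assert_array_equal(out.p, pt.p)


def test_leapfrog_reversibility_long_trajectory():
    """Forward L steps, negate momentum, forward L steps, negate: identity
    to 1e-10 — the reversibility of the symplectic scheme."""
    m = ln.mvn_model(np.zeros(4), 0.5 * np.eye(4) + 0.5)
    rng = np.random.default_rng(7)
    q0, p0 = rng.normal(size=4), rng.normal(size=4)
    metric = Metric.diag(np.array([0.5, 1.0, 2.0, 1.5]))
    pt = PhasePoint.at(q0, p0, m)
    for _ in range(50):
        pt = leapfrog(pt, 0.1, metric, m)
    pt = PhasePoint(pt.q, -pt.p, pt.logp, pt.grad)
    for _ in range(50):
        pt = leapfrog(pt, 0.1, metric, m)
    np.testing.assert_allclose(pt.q, q0, atol=1e-10)
    np.testing.assert_allclose(-pt.p, p0, atol=1e-10)


def test_energy_error_scales_as_eps_squared():
    """|ΔH| over a fixed integration time is O(eps^2): log-log slope in
    [1.8, 2.2] on a Gaussian target."""
    m = ln.mvn_model(np.zeros(5), np.eye(5))
    metric = Metric.unit(5)
    rng = np.random.default_rng(3)
    epss = np.array([0.05, 0.1, 0.2, 0.4])
    med = []
    for eps in epss:
        errs = []
        for _ in range(150):
            pt = PhasePoint.at(rng.normal(size=5), rng.normal(size=5), m)
            H0 = hamiltonian(pt, metric)
            for _ in range(int(round(1.0 / eps))):
                pt = leapfrog(pt, eps, metric, m)
            errs.append(abs(hamiltonian(pt, metric) - H0))
        med.append(np.median(errs))
    slope = np.polyfit(np.log(epss), np.log(med), 1)[0]
    assert 1.8 <= slope <= 2.2


def test_leapfrog_divergent_on_nonfinite_gradient():
    def lg(q):
        if abs(q[0]) > 1.0:
            return -math.inf, np.array([math.nan])
        return 0.0, np.zeros(1)

    m = FunctionModel([ParameterSpec("q")], lg)
    pt = PhasePoint.at(np.array([0.9]), np.array([5.0]), m)
    out = leapfrog(pt, 0.5, Metric.unit(1), m)
    assert out.logp == -math.inf


# -- U-turn ----------------------------------------------------------------

def _pp(q, p):
    return PhasePoint(np.atleast_1d(float(q)), np.atleast_1d(float(p)), 0.0, np.zeros(1))


@pytest.mark.parametrize(
    "qm,qp,pm,pp_,expected",
    [
        (0.0, 2.0, 1.0, 1.0, False),   # both projections +2
        (0.0, 2.0, 1.0, -1.0, True),   # right end turned back
        (0.0, 2.0, -1.0, 1.0, True),   # left end turned back
        (1.0, 1.0, 1.0, 1.0, False),   # coincident ends: 0 < 0 is false -> continue
    ],
)
def test_is_uturn_sign_convention(qm, qp, pm, pp_, expected):
    assert is_uturn(_pp(qm, pm), _pp(qp, pp_), Metric.unit(1)) is expected


# -- build_tree ------------------------------------------------------------

def test_build_tree_small_step_never_divergent():
    m = _std_normal()
    rng = np.random.default_rng(0)
    pt = PhasePoint.at(np.array([0.3]), np.array([0.5]), m)
    H0 = hamiltonian(pt, Metric.unit(1))
    log_u = math.log(rng.random()) - H0
    tree = build_tree(pt, log_u, 1, 0, 1e-4, Metric.unit(1), m, H0, rng)
    assert tree.n_valid in (0, 1)
    assert not tree.divergent
    assert tree.n_leapfrog == 1


def test_build_tree_huge_step_divergent():
    """eps = 20 on a standard normal blows the energy past the divergence
    threshold within a few doublings (oracle: direct leapfrog shows
    ΔH > 1000)."""
    m = _std_normal()
    rng = np.random.default_rng(1)
    pt = PhasePoint.at(np.zeros(1), np.array([1.0]), m)
    H0 = hamiltonian(pt, Metric.unit(1))
    # oracle: energy after a few manual eps=20 steps exceeds DELTA_MAX
    probe, maxH = pt, H0
    for _ in range(8):
        probe = leapfrog(probe, 20.0, Metric.unit(1), m)
        maxH = max(maxH, hamiltonian(probe, Metric.unit(1)))
    assert maxH - H0 > DELTA_MAX
    log_u = math.log(rng.random()) - H0
    divergent = False
    for depth in range(4):
        tree = build_tree(pt, log_u, 1, depth, 20.0, Metric.unit(1), m, H0, rng)
        divergent = divergent or tree.divergent
    assert divergent


def test_build_tree_stop_propagates_and_counts():
    m = _std_normal()
    rng = np.random.default_rng(2)
    pt = PhasePoint.at(np.array([0.0]), np.array([1.0]), m)
    H0 = hamiltonian(pt, Metric.unit(1))
    log_u = math.log(rng.random()) - H0
    # depth-3 subtree with a large-but-stable step: U-turn must occur
    tree = build_tree(pt, log_u, 1, 3, 1.4, Metric.unit(1), m, H0, rng)
    assert tree.n_valid <= 2 ** 3
    if tree.stop and not tree.divergent:
        # proposal must be a slice-valid state of the pre-stop trajectory
        H = hamiltonian(tree.proposal, Metric.unit(1))
        assert log_u <= -H or tree.n_valid == 0


# -- nuts_transition -------------------------------------------------------

def test_transition_moments_match_target():
    """20000 fixed-step transitions on N(0,1): mean and variance match the
    target within 3 MCSE."""
    from lapnuts.diagnostics import ess

    m = _std_normal()
    rng = np.random.default_rng(4)
    q = np.zeros(1)
    draws = np.empty(20000)
    for i in range(draws.size):
        q, _ = nuts_transition(q, 0.5, Metric.unit(1), m, 10, rng)
        draws[i] = q[0]
    e = float(ess(draws.reshape(2, -1))[0])
    mcse = 1.0 / math.sqrt(e)
    assert abs(draws.mean()) < 3 * mcse
    var_mcse = math.sqrt(2.0 / e)  # var of sample variance of N(0,1) ~ 2/n_eff
    assert abs(draws.var() - 1.0) < 3 * var_mcse


def test_max_treedepth_zero_forces_single_leapfrog():
    m = _std_normal()
    rng = np.random.default_rng(5)
    for _ in range(20):
        _, info = nuts_transition(np.array([0.2]), 0.3, Metric.unit(1), m, 0, rng)
        assert info.n_leapfrog == 1
        assert info.treedepth == 0


def test_divergent_transition_recorded_and_state_valid():
    m = _std_normal()
    rng = np.random.default_rng(6)
    q0 = np.array([0.1])
    q1, info = nuts_transition(q0, 25.0, Metric.unit(1), m, 10, rng)
    assert info.divergent == 1
    assert np.isfinite(q1).all()


def test_transition_rejects_nonfinite_start():
    m = FunctionModel([ParameterSpec("q")], lambda q: (-math.inf, np.zeros(1)))
    with pytest.raises(ValueError):
        nuts_transition(np.zeros(1), 0.5, Metric.unit(1), m, 5, np.random.default_rng(0))


def test_gradient_evaluations_equal_n_leapfrog_plus_one():
    calls = [0]

    def lg(q):
        calls[0] += 1
        return -0.5 * float(q @ q), -q

    m = FunctionModel([ParameterSpec("q")], lg)
    rng = np.random.default_rng(8)
    calls[0] = 0
    _, info = nuts_transition(np.array([0.4]), 0.4, Metric.unit(1), m, 10, rng)
    assert calls[0] == info.n_leapfrog + 1
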