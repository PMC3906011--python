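"""Observed influence model: counting, likelihood, influence fitting."""

import numpy as np
import pytest

from scpoim import experiments as ex
from scpoim.oim import (
    OIMParams,
    best_ordering_score,
    count_transitions,
    fit_influence,
    fit_oim,
    log_likelihood,
    project_to_simplex,
    sample_labels,
)


def test_count_transitions_hand_examples():
    labels = np.array([[1, 2, 1, 2, 1]])
    A, pi, _ = count_transitions(labels, 3)
    assert A[0, 0, 0, 1] == 1.0 and A[0, 0, 1, 0] == 1.0
    np.testing.assert_allclose(A[0, 0, 2], 1.0 / 3)  # unvisited row -> uniform
    np.testing.assert_allclose(pi[0], [3 / 5, 2 / 5, 0])

    A, _, _ = count_transitions(np.array([[3, 3, 3]]), 3)
    assert A[0, 0, 2, 2] == 1.0

    with pytest.raises(ValueError):
        count_transitions(np.array([[1]]), 3)


def test_count_transitions_recovers_self_consistent_model():
    oim = ex.recovery_influence_model()
    labels = sample_labels(oim, 10000, 1)
    A, pi, _ = count_transitions(labels, 6)
    assert np.abs(A - oim.A).max() < 0.05


def test_likelihood_identity_theta_collapses_to_independent_chains():
    oim = ex.base_influence_model()
    labels = sample_labels(oim, 400, 3)
    ident = OIMParams(A=oim.A, theta=np.eye(2), pi=oim.pi)
    ll = log_likelihood(labels, ident)
    oracle = 0.0
    for c in range(2):
        oracle += np.log(oim.pi[c, labels[c, 0] - 1])
        for r in range(1, labels.shape[1]):
            oracle += np.log(oim.A[c, c, labels[c, r - 1] - 1, labels[c, r] - 1])
    assert abs(ll - oracle) < 1e-10


def test_likelihood_uniform_matrices_closed_form():
    N, C, R = 4, 2, 9
    rng = np.random.default_rng(0)
    labels = rng.integers(1, N + 1, size=(C, R))
    pi = np.full((C, N), 1.0 / N)
    params = OIMParams(
        A=np.full((C, C, N, N), 1.0 / N), theta=np.array([[0.3, 0.8], [0.7, 0.2]]), pi=pi
    )
    expected = (R - 1) * C * np.log(1.0 / N) + C * np.log(1.0 / N)
    assert log_likelihood(labels, params) == pytest.approx(expected)


def test_likelihood_matches_brute_force_on_toy():
    # 5-step dyad, N=2: term-by-term mixture product computed independently.
    rng = np.random.default_rng(5)
    N, C = 2, 2
    A = rng.dirichlet(np.ones(N), size=(C, C, N))
    theta = np.array([[0.6, 0.1], [0.4, 0.9]])
    pi = rng.dirichlet(np.ones(N), size=C)
    params = OIMParams(A=A, theta=theta, pi=pi)
    labels = np.array([[1, 2, 2, 1, 2], [2, 2, 1, 1, 1]])
    prob = 1.0
    for c in range(C):
        prob *= pi[c, labels[c, 0] - 1]
    for r in range(1, 5):
        for c in range(C):
            mix = 0.0
            for src in range(C):
                mix += theta[src, c] * A[src, c, labels[src, r - 1] - 1, labels[c, r] - 1]
            prob *= mix
    assert log_likelihood(labels, params) == pytest.approx(np.log(prob))


def test_zero_probability_gives_minus_inf_not_error():
    N = 2
    A = np.zeros((1, 1, N, N))
    A[0, 0] = np.eye(N)  # transitions 1->2 impossible
    pi = np.array([[1.0, 0.0]])
    params = OIMParams(A=A, theta=np.ones((1, 1)), pi=pi)
    assert log_likelihood(np.array([[1, 2]]), params) == -np.inf


def test_fit_influence_finds_planted_inter_chain_driver():
    # Chain 2 is a deterministic copy of chain 1's previous state.
    rng = np.random.default_rng(0)
    R, N = 2000, 4
    c1 = rng.integers(1, N + 1, R)
    c2 = np.empty(R, dtype=int)
    c2[0] = 1
    c2[1:] = c1[:-1]
    labels = np.stack([c1, c2])
    A, pi, _ = count_transitions(labels, N)
    theta, report = fit_influence(labels, A, pi)
    assert theta[0, 1] >= 0.95  # chain 1 drives chain 2
    for trace in report.traces:
        assert np.all(np.diff(trace) >= -1e-10)


def test_fit_influence_recovers_identity_influence():
    oim = ex.recovery_influence_model()
    self_weights = []
    for seed in range(20):
        labels = sample_labels(oim, 2000, seed)
        A, pi, _ = count_transitions(labels, 6)
        theta, _ = fit_influence(labels, A, pi)
        self_weights.append(min(theta[0, 0], theta[1, 1]))
    assert np.median(self_weights) >= 0.8


def test_fit_influence_rejects_non_simplex_init():
    labels = np.array([[1, 2, 1], [2, 1, 2]])
    A, pi, _ = count_transitions(labels, 2)
    with pytest.raises(ValueError):
        fit_influence(labels, A, pi, init_theta=np.array([[0.5, 1.2], [0.5, -0.2]]))


def test_fit_oim_parameter_count_and_determinism():
    oim = ex.base_influence_model()
    labels = sample_labels(oim, 300, 9)
    p1, _ = fit_oim(labels, 6)
    p2, _ = fit_oim(labels, 6)
    assert p1.n_parameters == 160
    np.testing.assert_array_equal(p1.theta, p2.theta)
    np.testing.assert_array_equal(p1.A, p2.A)
    p1.validate(atol=1e-9)  # stochasticity holds exactly after fitting


def test_fitted_influence_dominates_uniform_influence():
    oim = ex.base_influence_model()
    labels = sample_labels(oim, 500, 13)
    fitted, _ = fit_oim(labels, 6)
    uniform = OIMParams(A=fitted.A, theta=np.full((2, 2), 0.5), pi=fitted.pi)
    assert log_likelihood(labels, fitted) >= log_likelihood(labels, uniform) - 1e-9


def test_single_chain_reduces_to_markov_likelihood():
    rng = np.random.default_rng(2)
    N, R = 3, 50
    A = rng.dirichlet(np.ones(N), size=(1, 1, N))
    pi = rng.dirichlet(np.ones(N), size=1)
    params = OIMParams(A=A, theta=np.ones((1, 1)), pi=pi)
    labels = sample_labels(params, R, 0)
    markov = np.log(pi[0, labels[0, 0] - 1]) + sum(
        np.log(A[0, 0, labels[0, r - 1] - 1, labels[0, r] - 1]) for r in range(1, R)
    )
    assert log_likelihood(labels, params) == pytest.approx(markov, abs=1e-12)


def test_best_ordering_symmetric_model_ties_to_first():
    N = 2
    sym = np.array([[0.7, 0.3], [0.4, 0.6]])
    A = np.stack([np.stack([sym, sym]), np.stack([sym, sym])])
    pi = np.full((2, N), 0.5)
    params = OIMParams(A=A, theta=np.full((2, 2), 0.5), pi=pi)
    labels = np.array([[1, 2, 1], [2, 1, 2]])
    ll, ordering = best_ordering_score(labels, params)
    assert ordering == 0
    assert ll == pytest.approx(log_likelihood(labels, params))


def test_best_ordering_beats_single_orderings_and_detects_asymmetry():
    base = ex.base_influence_model()
    wins = 0
    for seed in range(50):
        labels = sample_labels(base, 300, 100 + seed)
        fitted, _ = fit_oim(labels, 6)
        ll, ordering = best_ordering_score(labels, fitted)
        assert ll >= log_likelihood(labels, fitted) - 1e-12
        assert ll >= log_likelihood(labels[::-1], fitted) - 1e-12
        wins += ordering == 0
    assert wins >= 45  # correct ordering in >= 90% of dyads


def test_simplex_projection_properties():
    rng = np.random.default_rng(0)
    for _ in range(100):
        v = rng.normal(size=4) * 10
        p = project_to_simplex(v)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(project_to_simplex(np.array([0.2, 0.3, 0.5])), [0.2, 0.3, 0.5])
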