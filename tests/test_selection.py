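"""Feature selection policies and stability ranking against oracles."""

import itertools

import numpy as np
import pytest

from scpoim.classify import knn_loo_mean_recall
from scpoim.selection import (
    _mutual_information,
    branch_and_bound_selection,
    forward_selection,
    mrmr_selection,
    separability_criterion,
    stability_rank,
)


def _two_class_labels(n_per=9):
    return np.array(["a"] * n_per + ["b"] * n_per)


def _noise_matrix(rng, n, F, scale=1.0):
    return rng.normal(scale=scale, size=(n, F))


# ---------------------------------------------------------------------------
# forward selection

def test_forward_picks_perfect_separator_first():
    rng = np.random.default_rng(0)
    y = _two_class_labels()
    X = _noise_matrix(rng, 18, 21)
    X[:, 7] = np.where(y == "a", -5.0, 5.0) + rng.normal(scale=0.1, size=18)
    subset = forward_selection(X, y, T=3)
    assert subset[0] == 7
    assert len(subset) <= 3


def test_forward_matches_exhaustive_best_pair_on_constructed_toy():
    # Two complementary informative features among noise, built so that the
    # greedy path coincides with the exhaustive best pair.
    rng = np.random.default_rng(11)
    y = _two_class_labels()
    X = _noise_matrix(rng, 18, 6)
    signal = np.where(y == "a", -1.0, 1.0)
    X[:, 1] = signal + rng.normal(scale=0.9, size=18)
    X[:, 4] = signal + rng.normal(scale=0.9, size=18)
    greedy = forward_selection(X, y, T=2)
    best_pair, best_val = None, -np.inf
    for pair in itertools.combinations(range(6), 2):
        val = knn_loo_mean_recall(X[:, pair], y)
        if val > best_val:
            best_pair, best_val = set(pair), val
    assert set(greedy) == best_pair == {1, 4}


def test_forward_respects_T_and_rejects_single_class():
    rng = np.random.default_rng(1)
    X = _noise_matrix(rng, 10, 8)
    y = _two_class_labels(5)
    assert len(forward_selection(X, y, T=4)) <= 4
    with pytest.raises(ValueError):
        forward_selection(X, np.array(["a"] * 10), T=2)


def test_forward_accepts_custom_wrapper():
    rng = np.random.default_rng(2)
    y = _two_class_labels(5)
    X = _noise_matrix(rng, 10, 5)
    X[:, 2] = np.where(y == "a", 0.0, 10.0)

    def variance_ratio(Xs, ys):  # crude separability wrapper
        return separability_criterion(Xs, ys, None)

    assert forward_selection(X, y, T=1, wrapper=variance_ratio) == [2]


# ---------------------------------------------------------------------------
# branch and bound

def test_separability_criterion_is_monotone_under_feature_addition():
    rng = np.random.default_rng(4)
    X = _noise_matrix(rng, 14, 8)
    y = _two_class_labels(7)
    for _ in range(50):
        sub = sorted(rng.choice(8, size=rng.integers(1, 7), replace=False).tolist())
        sup = sorted(set(sub) | set(rng.choice(8, size=2, replace=False).tolist()))
        assert separability_criterion(X, y, sup) >= separability_criterion(X, y, sub) - 1e-9


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_branch_and_bound_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    y = _two_class_labels(7)
    X = _noise_matrix(rng, 14, 10)
    X[:, 2] += np.where(y == "a", -0.8, 0.8)
    X[:, 6] += np.where(y == "a", 0.6, -0.6)
    got = branch_and_bound_selection(X, y, T=3)
    best, best_val = None, -np.inf
    for sub in itertools.combinations(range(10), 3):
        val = separability_criterion(X, y, list(sub))
        if val > best_val + 1e-12:
            best, best_val = sorted(sub), val
    assert got == best


def test_branch_and_bound_keeps_one_of_two_duplicated_features():
    rng = np.random.default_rng(7)
    y = _two_class_labels(8)
    X = _noise_matrix(rng, 16, 7)
    strong = np.where(y == "a", -1.5, 1.5) + rng.normal(scale=0.3, size=16)
    X[:, 1] = strong
    X[:, 3] = strong  # exact duplicate
    X[:, 5] += np.where(y == "a", -0.7, 0.7)
    X[:, 6] += np.where(y == "a", 0.5, -0.5)
    got = branch_and_bound_selection(X, y, T=3)
    assert 1 in got and 3 not in got  # tie resolves to the lower index


def test_branch_and_bound_prefilters_large_inputs():
    rng = np.random.default_rng(8)
    y = _two_class_labels(9)
    X = _noise_matrix(rng, 18, 40)
    X[:, 31] += np.where(y == "a", -2.0, 2.0)
    got = branch_and_bound_selection(X, y, T=3, max_exact_features=12)
    assert len(got) == 3
    assert 31 in got
    with pytest.raises(ValueError):
        branch_and_bound_selection(X[:, :2], y, T=3)


# ---------------------------------------------------------------------------
# mRMR

def test_mrmr_selects_informative_feature_first():
    rng = np.random.default_rng(9)
    y = _two_class_labels()
    X = _noise_matrix(rng, 18, 10)
    X[:, 4] = np.where(y == "a", 0.0, 1.0) + rng.normal(scale=0.05, size=18)
    assert mrmr_selection(X, y, T=3)[0] == 4


def test_mrmr_defers_exact_copy_behind_weaker_independent_feature():
    rng = np.random.default_rng(10)
    y = _two_class_labels()
    X = _noise_matrix(rng, 18, 5)
    info = np.where(y == "a", 0.0, 1.0) + rng.normal(scale=0.05, size=18)
    X[:, 0] = info
    X[:, 1] = info  # exact copy: fully redundant with feature 0
    X[:, 3] = np.where(y == "a", 0.0, 1.0) + rng.normal(scale=0.8, size=18)
    order = mrmr_selection(X, y, T=5)
    assert order[0] == 0
    assert order.index(3) < order.index(1)


def test_constant_feature_never_precedes_informative_one():
    rng = np.random.default_rng(11)
    y = _two_class_labels(5)
    X = _noise_matrix(rng, 10, 4)
    X[:, 0] = 1.0  # constant
    X[:, 2] = np.where(y == "a", 0.0, 1.0)
    order = mrmr_selection(X, y, T=4)
    assert order.index(2) < order.index(0)


def test_self_information_dominates_cross_information():
    rng = np.random.default_rng(12)
    a = rng.integers(0, 3, 30)
    b = rng.integers(0, 3, 30)
    assert _mutual_information(a, a) >= _mutual_information(a, b) - 1e-12


# ---------------------------------------------------------------------------
# stability ranking

def test_instance_bookkeeping_for_18_samples_three_policies():
    rng = np.random.default_rng(13)
    y = _two_class_labels()
    X = _noise_matrix(rng, 18, 12)
    ranking = stability_rank(X, y, T=3)
    assert ranking.n_instances == 54  # 18 folds x 3 policies
    assert all(v == 18 for v in ranking.instances_per_policy().values())
    # recount oracle: stored instances reproduce counts and frequencies
    recount = np.zeros(12)
    for inst in ranking.instances:
        assert len(inst.features) <= 3
        for f in inst.features:
            recount[f] += 1
    np.testing.assert_array_equal(recount, ranking.counts)
    np.testing.assert_allclose(ranking.frequencies, recount / 54)
    assert ranking.frequencies.min() >= 0 and ranking.frequencies.max() <= 1


def test_feature_selected_everywhere_gets_frequency_one_and_rank_one():
    rng = np.random.default_rng(14)
    y = _two_class_labels()
    X = _noise_matrix(rng, 18, 10)
    X[:, 6] = np.where(y == "a", -4.0, 4.0) + rng.normal(scale=0.1, size=18)
    ranking = stability_rank(X, y, T=2)
    assert ranking.frequencies[6] == 1.0
    assert ranking.order[0] == 6


def test_planted_score_level_features_take_top_two_ranks():
    # Class difference confined to exactly two features (score-level plant):
    # those two must occupy the top-2 ranks in >= 80% of replicates.
    y = _two_class_labels()
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(100 + rep)
        X = _noise_matrix(rng, 18, 160, scale=0.1)
        X[y == "b"][:, :]  # no-op, clarity only
        X[np.ix_(y == "b", [4, 16])] += 0.3
        ranking = stability_rank(X, y, T=10)
        hits += set(ranking.order[:2]) == {4, 16}
    assert hits >= 16
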