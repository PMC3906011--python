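"""K-NN, linear SVM, LOO/resubstitution evaluation, curves and grids."""

import numpy as np
import pytest

from scpoim.classify import (
    accuracy_curve,
    decision_boundary_grid,
    knn_predict,
    linear_svm,
    loo_evaluate,
    separation_evaluate,
)


def _planted_scores(rng, n_per=9, F=20, shift=1.5, scale=1.0):
    y = np.array(["a"] * n_per + ["b"] * n_per)
    X = rng.normal(scale=scale, size=(2 * n_per, F))
    X[np.ix_(y == "b", [0, 1])] += shift
    return X, y


# ---------------------------------------------------------------------------
# K-NN

def test_knn_trivial_votes():
    X = np.array([[0.0], [0.0], [0.0], [5.0]])
    y = np.array(["a", "a", "a", "b"])
    assert knn_predict(X, y, np.array([0.0]), K=3) == "a"
    X = np.array([[0.0], [0.1], [5.0]])
    y = np.array(["a", "a", "b"])
    assert knn_predict(X, y, np.array([0.2]), K=3) == "a"  # 2-vs-1 majority


def test_knn_tie_rules_are_deterministic():
    # Distance tie: two training points equidistant; lower index must win.
    X = np.array([[1.0], [-1.0], [9.0]])
    y = np.array(["a", "b", "b"])
    assert knn_predict(X, y, np.array([0.0]), K=1) == "a"
    # Vote tie (K=2): class of the single nearest neighbor decides.
    X = np.array([[1.0], [2.0]])
    y = np.array(["b", "a"])
    assert knn_predict(X, y, np.array([0.5]), K=2) == "b"


def test_knn_agrees_with_brute_force_scan():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    y = np.array(["a", "b"] * 15)
    queries = rng.normal(size=(200, 4))
    for q in queries:
        d = np.sqrt(((X - q) ** 2).sum(axis=1))
        order = sorted(range(30), key=lambda i: (d[i], i))[:3]
        votes = [y[i] for i in order]
        # two classes and K=3: the majority is always well defined
        expected = max(set(votes), key=votes.count)
        assert knn_predict(X, y, q, K=3) == expected


def test_knn_rejects_k_larger_than_train():
    with pytest.raises(ValueError):
        knn_predict(np.zeros((2, 1)), np.array(["a", "b"]), np.zeros(1), K=3)


# ---------------------------------------------------------------------------
# linear SVM

def test_svm_symmetric_toy_boundary_at_zero():
    X = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
    y = np.array(["a", "a", "b", "b"])
    clf = linear_svm(X, y)
    w, b = clf.coef_[0], clf.intercept_[0]
    assert abs(-b / w[0]) < 1e-6  # boundary x = 0
    assert abs(w[1]) < 1e-6


def test_svm_margin_matches_closed_form_on_four_points():
    # Hard-margin solution: w = (1, 0), margin width 2/||w|| = 2.
    X = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
    y = np.array(["a", "a", "b", "b"])
    clf = linear_svm(X, y, C=1.0)
    margin = 2.0 / np.linalg.norm(clf.coef_[0])
    assert margin == pytest.approx(2.0, abs=1e-6)


def test_svm_scaling_preserves_sign_pattern():
    rng = np.random.default_rng(1)
    X, y = _planted_scores(rng, n_per=6, F=2, shift=3.0)
    p1 = linear_svm(X, y).predict(X)
    p2 = linear_svm(2 * X, y).predict(2 * X)
    np.testing.assert_array_equal(p1, p2)


def test_svm_requires_two_classes():
    with pytest.raises(ValueError):
        linear_svm(np.zeros((4, 2)), np.array(["a"] * 4))


# ---------------------------------------------------------------------------
# LOO evaluation

def test_loo_perfect_separation_gives_unit_metrics():
    rng = np.random.default_rng(2)
    X, y = _planted_scores(rng, shift=30.0, scale=0.3)
    for clf in ("knn", "svm"):
        rep = loo_evaluate(X, y, [0, 1], clf)
        assert rep.mean_recall == 1.0
        assert all(v == 1.0 for v in rep.precision.values())
        assert all(v == 1.0 for v in rep.recall.values())


def test_loo_fold_count_equals_sample_count():
    rng = np.random.default_rng(3)
    X, y = _planted_scores(rng)
    rep = loo_evaluate(X, y, [0, 1], "knn")
    assert len(rep.predictions) == 18


def test_loo_identical_features_score_at_chance():
    recalls = []
    for rep_i in range(20):
        rng = np.random.default_rng(200 + rep_i)
        X = np.zeros((18, 3))
        X += rng.normal(scale=1e-9, size=X.shape)  # break exact ties randomly
        y = rng.permutation(np.array(["a"] * 9 + ["b"] * 9))
        recalls.append(loo_evaluate(X, y, None, "knn").mean_recall)
    assert abs(np.mean(recalls) - 0.5) <= 0.15


def test_report_self_audit_matches_stored_metrics():
    rng = np.random.default_rng(4)
    X, y = _planted_scores(rng, shift=1.0)
    rep = loo_evaluate(X, y, [0, 1, 2], "svm")
    precision, recall, mean_recall = rep.recompute_metrics()
    assert precision == rep.precision and recall == rep.recall
    assert mean_recall == rep.mean_recall


# ---------------------------------------------------------------------------
# accuracy curve

def test_accuracy_curve_on_two_informative_features():
    rng = np.random.default_rng(5)
    X, y = _planted_scores(rng, F=30, shift=1.6)
    ranking = [0, 1] + list(range(2, 30))
    curve = accuracy_curve(X, y, ranking, k_max=5, classifiers=("knn",))["knn"]
    assert len(curve) == 5
    assert curve[1] > curve[0]  # the second planted feature helps
    assert np.argmax(curve) >= 1  # maximum attained at k >= 2


def test_accuracy_curve_on_pure_noise_hovers_at_chance():
    rng = np.random.default_rng(6)
    y = np.array(["a"] * 9 + ["b"] * 9)
    X = rng.normal(size=(18, 12))
    curve = accuracy_curve(X, y, list(range(12)), k_max=8, classifiers=("knn",))["knn"]
    assert abs(curve.mean() - 0.5) <= 0.2


# ---------------------------------------------------------------------------
# separation (resubstitution)

def test_separation_separable_toy_is_perfect():
    rng = np.random.default_rng(7)
    X, y = _planted_scores(rng, shift=30.0, scale=0.3)
    for clf in ("knn", "svm"):
        rep = separation_evaluate(X, y, [0, 1], clf)
        assert rep.mode == "resubstitution"
        assert rep.mean_recall == 1.0


def test_resubstitution_is_optimistic_relative_to_loo(planted_study):
    # On planted cohorts the resubstitution score should dominate the LOO
    # score in nearly every replicate (both classifiers).
    wins = 0
    for r in planted_study:
        top2 = r.pooled_order[:2]
        loo = loo_evaluate(r.scores, r.labels, top2, "svm").mean_recall
        resub = separation_evaluate(r.scores, r.labels, top2, "svm").mean_recall
        wins += resub >= loo
    assert wins >= 18  # >= 90% of 20 replicates


# ---------------------------------------------------------------------------
# decision boundary grid

def test_grid_has_resolution_squared_nodes_and_linear_boundary():
    rng = np.random.default_rng(8)
    X, y = _planted_scores(rng, F=2, shift=6.0, scale=0.4)
    grid = decision_boundary_grid(X, y, "svm", resolution=40)
    assert grid.labels.shape == (40, 40)
    # linear separator: along each grid row the label changes at most once
    for row in grid.labels:
        changes = np.sum(row[1:] != row[:-1])
        assert changes <= 1


def test_training_points_carry_their_resubstitution_label_on_the_grid():
    rng = np.random.default_rng(9)
    X, y = _planted_scores(rng, F=2, shift=8.0, scale=0.5)
    rep = separation_evaluate(X, y, None, "svm")
    grid = decision_boundary_grid(X, y, "svm", resolution=120)
    for i, (x1, x2) in enumerate(X):
        ix = np.argmin(np.abs(grid.x - x1))
        iy = np.argmin(np.abs(grid.y - x2))
        assert grid.labels[iy, ix] == rep.predictions[i]


def test_grid_rejects_non_2d_input():
    with pytest.raises(ValueError):
        decision_boundary_grid(np.zeros((6, 3)), np.array(["a", "b"] * 3), "knn")
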