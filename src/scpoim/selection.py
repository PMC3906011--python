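"""Stability-based feature selection over the generative score space.

Three selection policies are provided — greedy forward selection wrapped
around the K-NN classifier (K = 3, inner leave-one-out mean recall),
branch-and-bound search under a monotone scatter-based separability
criterion, and minimum-redundancy maximum-relevance on 3-bin discretized
features — and a stability ranking that runs every policy inside a
leave-one-out loop and scores each feature by how often it appears across
all produced instances.

Ties everywhere resolve to the lowest feature index, so every policy is
deterministic given its inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import _binary_codes, _loo_knn_mean_recall_from_d2

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionInstance",
    "FeatureRanking",
    "forward_selection",
    "branch_and_bound_selection",
    "mrmr_selection",
    "stability_rank",
    "separability_criterion",
    "DEFAULT_POLICIES",
]


# ---------------------------------------------------------------------------
# forward selection (wrapper: inner-LOO K-NN mean recall)

def forward_selection(scores: np.ndarray, labels: np.ndarray, T: int = 10, wrapper=None, K: int = 3):
    """Greedy add-one-at-a-time maximization of the wrapper criterion.

    The default wrapper is the inner leave-one-out mean recall of the K-NN
    classifier (K = 3) on the provided samples.  Selection stops at ``T``
    features or as soon as no addition strictly improves the criterion.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("forward selection needs at least two classes")
    n, F = X.shape

    if wrapper is not None:
        selected: list[int] = []
        best = -np.inf
        while len(selected) < min(T, F):
            cand = [f for f in range(F) if f not in selected]
            vals = np.array([wrapper(X[:, selected + [f]], y) for f in cand])
            j = int(np.argmax(vals))  # first maximum: lowest index wins ties
            if vals[j] <= best:
                break
            selected.append(cand[j])
            best = vals[j]
        return selected

    codes, _ = _binary_codes(y)
    diffs = (X[:, None, :] - X[None, :, :]) ** 2  # (n, n, F)
    diffs = np.moveaxis(diffs, -1, 0)  # (F, n, n)
    D_base = np.zeros((n, n))
    selected = []
    best = -np.inf
    remaining = list(range(F))
    while len(selected) < min(T, F) and remaining:
        vals = _loo_knn_mean_recall_from_d2(D_base[None] + diffs[remaining], codes, K)
        j = int(np.argmax(vals))
        if vals[j] <= best:
            break
        f = remaining[j]
        selected.append(f)
        best = float(vals[j])
        D_base = D_base + diffs[f]
        remaining.remove(f)
    return selected


# ---------------------------------------------------------------------------
# branch and bound (monotone scatter-based separability criterion)

def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    grand = X.mean(axis=0)
    F = X.shape[1]
    Sw = np.zeros((F, F))
    Sb = np.zeros((F, F))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        Sw += dev.T @ dev
        d = (mc - grand)[:, None]
        Sb += Xc.shape[0] * (d @ d.T)
    return Sw, Sb


def separability_criterion(X: np.ndarray, y: np.ndarray, subset=None, ridge: float = 1e-6) -> float:
    """trace((Sw + ridge I)^-1 Sb) on a feature subset.

    With the ridge applied to the full within-class scatter, the criterion
    of a subset uses the corresponding principal submatrix, which makes the
    value monotone non-decreasing under feature addition — the property the
    branch-and-bound search requires for its bound to be exact.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Sw, Sb = _scatter_matrices(X, y)
    return _criterion_from_scatter(Sw, Sb, list(subset) if subset is not None else None, ridge)


def _criterion_from_scatter(Sw, Sb, subset, ridge) -> float:
    if subset is None:
        subset = list(range(Sw.shape[0]))
    if not subset:
        return 0.0
    ix = np.ix_(subset, subset)
    M = Sw[ix] + ridge * np.eye(len(subset))
    try:
        val = float(np.trace(np.linalg.solve(M, Sb[ix])))
    except np.linalg.LinAlgError:
        logger.debug("singular within-class scatter; extra ridge applied")
        M = M + 1e-6 * np.eye(len(subset))
        val = float(np.trace(np.linalg.solve(M, Sb[ix])))
    return val


def branch_and_bound_selection(
    scores: np.ndarray,
    labels: np.ndarray,
    T: int = 10,
    ridge: float = 1e-6,
    max_exact_features: int = 12,
):
    """Optimal T-subset under the monotone separability criterion.

    Backward search: starting from the full feature set, features are
    removed one at a time; because the criterion never increases when a
    feature is dropped, any partial set whose criterion already falls below
    the best complete T-subset can be pruned — so the search returns the
    same subset as exhaustive enumeration.  Exact search is exponential in
    the worst case; above ``max_exact_features`` features the candidate
    pool is first reduced to the individually best ``max_exact_features``
    features under the same criterion, and the exact search runs inside
    that pool.

    Ties (equal criterion) resolve to the lexicographically smallest index
    set.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    F = X.shape[1]
    if F < T:
        raise ValueError(f"need at least T={T} features, got {F}")
    Sw, Sb = _scatter_matrices(X, y)
    eps = 1e-12

    if F > max_exact_features:
        singles = np.diag(Sb) / (np.diag(Sw) + ridge)
        pool = sorted(np.argsort(-singles, kind="stable")[:max_exact_features].tolist())
    else:
        pool = list(range(F))
    if len(pool) == T:
        return pool

    def J(subset: list[int]) -> float:
        return _criterion_from_scatter(Sw, Sb, subset, ridge)

    # initial bound: backward greedy
    S = list(pool)
    while len(S) > T:
        drops = [J(S[:p] + S[p + 1 :]) for p in range(len(S))]
        p = int(np.argmax(drops))
        S = S[:p] + S[p + 1 :]
    best = {"J": J(S), "S": sorted(S)}

    def consider(S: list[int]) -> None:
        val = J(S)
        key = sorted(S)
        if val > best["J"] + eps or (val >= best["J"] - eps and key < best["S"]):
            best["J"], best["S"] = max(val, best["J"]), key

    def recurse(S: list[int], start: int) -> None:
        if len(S) == T:
            consider(S)
            return
        need = len(S) - T
        children = []
        for p in range(start, len(S) - need + 1):
            child = S[:p] + S[p + 1 :]
            children.append((J(child), p, child))
        children.sort(key=lambda t: (-t[0], t[1]))
        for val, p, child in children:
            if val < best["J"] - eps:
                continue  # monotone bound: no completion can beat the best
            recurse(child, p)

    recurse(list(pool), 0)
    return best["S"]


# ---------------------------------------------------------------------------
# minimum redundancy, maximum relevance

def _discretize(X: np.ndarray, bins: int = 3) -> np.ndarray:
    """Equal-frequency binning per feature; constant features get one bin."""
    n, F = X.shape
    B = np.zeros((n, F), dtype=np.int8)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for f in range(F):
        cuts = np.quantile(X[:, f], qs)
        B[:, f] = np.searchsorted(cuts, X[:, f], side="right")
    return B


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small discrete code arrays."""
    return float(_mi_against(b.reshape(-1, 1), a)[0])


def _mi_against(B: np.ndarray, t: np.ndarray) -> np.ndarray:
    """MI (nats) of every column of code matrix ``B`` with code vector ``t``."""
    t = np.asarray(t)
    mi = np.zeros(B.shape[1])
    for a in np.unique(t):
        ta = t == a
        pa = ta.mean()
        for b in np.unique(B):
            Bb = B == b
            pab = (ta[:, None] & Bb).mean(axis=0)
            pb = Bb.mean(axis=0)
            nz = pab > 0
            mi[nz] += pab[nz] * np.log(pab[nz] / (pa * pb[nz]))
    return np.maximum(mi, 0.0)


def mrmr_selection(scores: np.ndarray, labels: np.ndarray, T: int = 10, bins: int = 3):
    """Greedy mRMR on equal-frequency-binned features.

    Score of a candidate = MI(feature; class) minus the mean MI between the
    feature and the already-selected set.  A constant feature has zero MI
    with everything, so it can never precede an informative feature.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    ycodes = np.searchsorted(np.unique(y), y)
    n, F = X.shape
    B = _discretize(X, bins)
    relevance = _mi_against(B, ycodes)

    selected = [int(np.argmax(relevance))]  # first maximum: lowest index
    red = np.zeros(F)
    while len(selected) < min(T, F):
        red += _mi_against(B, B[:, selected[-1]])
        score = relevance - red / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


# ---------------------------------------------------------------------------
# stability ranking

DEFAULT_POLICIES = ("forward", "branch_and_bound", "mrmr")

_POLICY_FUNCS = {
    "forward": forward_selection,
    "branch_and_bound": branch_and_bound_selection,
    "mrmr": mrmr_selection,
}


@dataclass
class SelectionInstance:
    policy: str
    fold: int
    features: tuple


@dataclass
class FeatureRanking:
    """Frequency-scored features pooled over policies and LOO folds."""

    counts: np.ndarray
    frequencies: np.ndarray
    order: list
    instances: list = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def instances_per_policy(self) -> dict:
        out: dict[str, int] = {}
        for inst in self.instances:
            out[inst.policy] = out.get(inst.policy, 0) + 1
        return out


def stability_rank(
    scores: np.ndarray,
    labels: np.ndarray,
    policies=DEFAULT_POLICIES,
    T: int = 10,
    **policy_kwargs,
) -> FeatureRanking:
    """Rank features by their selection frequency across policies and folds.

    Each policy runs once per leave-one-out fold on the n-1 retained
    samples (the held-out sample is never seen by the policy), producing
    n instances per policy.  All instances are pooled; each feature's
    frequency is its appearance count divided by the total instance count.
    The ordering is by descending frequency, ties by ascending index.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n, F = X.shape
    classes = np.unique(y)
    if any(np.sum(y == c) < 2 for c in classes):
        raise ValueError("need at least two samples per class")
    instances = []
    for pol in policies:
        func = _POLICY_FUNCS[pol] if isinstance(pol, str) else pol
        name = pol if isinstance(pol, str) else getattr(pol, "__name__", "custom")
        for i in range(n):
            mask = np.arange(n) != i
            subset = func(X[mask], y[mask], T, **policy_kwargs.get(name, {}))
            if len(subset) > T:
                raise RuntimeError(f"policy {name} returned more than T features")
            instances.append(SelectionInstance(policy=name, fold=i, features=tuple(subset)))
    counts = np.zeros(F)
    for inst in instances:
        for f in inst.features:
            counts[f] += 1
    freqs = counts / len(instances)
    order = sorted(range(F), key=lambda f: (-freqs[f], f))
    return FeatureRanking(counts=counts, frequencies=freqs, order=order, instances=instances)
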