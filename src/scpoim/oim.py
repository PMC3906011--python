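"""Observed influence model (OIM) for coupled first-order Markov chains.

The OIM factorizes the joint transition probability of C interacting chains
with N states each as, for every target chain c,

    P(S_t^c = j | S_{t-1}^1, ..., S_{t-1}^C)
        = sum_{c'} theta_{c'c} * A^(c'c)[S_{t-1}^{c'}, j]

where A^(c'c) is the (intra-chain if c'=c, inter-chain otherwise) transition
matrix and the nonnegative influence weights theta_{.c} sum to one.  The
transition matrices and initial distributions are estimated by state
counting; the influence weights by constrained (projected) gradient ascent
on the log-likelihood, which is concave in each theta column.

The model is "observed" in the sense that the chain states are directly
observed labels, not hidden states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OIMParams",
    "FitReport",
    "count_transitions",
    "log_likelihood",
    "fit_influence",
    "fit_oim",
    "best_ordering_score",
    "project_to_simplex",
    "sample_labels",
]


@dataclass
class OIMParams:
    """Parameters of an observed influence model.

    Attributes
    ----------
    A : ndarray, shape (C, C, N, N)
        ``A[src, tgt, i, j]`` is the probability that chain ``tgt`` is in
        state ``j+1`` at step ``r`` given chain ``src`` was in state ``i+1``
        at step ``r-1``.  Every row ``A[src, tgt, i, :]`` is a probability
        distribution.
    theta : ndarray, shape (C, C)
        Influence weights; ``theta[src, tgt]`` is the influence of chain
        ``src`` on chain ``tgt``.  Each column sums to one.
    pi : ndarray, shape (C, N)
        Initial state distribution of each chain.
    """

    A: np.ndarray
    theta: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.validate()

    @property
    def n_chains(self) -> int:
        return self.A.shape[0]

    @property
    def n_states(self) -> int:
        return self.A.shape[2]

    @property
    def n_parameters(self) -> int:
        """Total parameter count C^2 N^2 + C^2 + C N (160 for N=6, C=2)."""
        C, N = self.n_chains, self.n_states
        return C * C * N * N + C * C + C * N

    def validate(self, atol: float = 1e-9) -> None:
        C = self.A.shape[0]
        N = self.A.shape[2]
        if self.A.shape != (C, C, N, N):
            raise ValueError(f"A must have shape (C, C, N, N), got {self.A.shape}")
        if self.theta.shape != (C, C):
            raise ValueError(f"theta must have shape ({C}, {C}), got {self.theta.shape}")
        if self.pi.shape != (C, N):
            raise ValueError(f"pi must have shape ({C}, {N}), got {self.pi.shape}")
        if np.any(self.A < -atol) or np.any(self.theta < -atol) or np.any(self.pi < -atol):
            raise ValueError("probabilities must be nonnegative")
        rows = self.A.sum(axis=3)
        if not np.allclose(rows, 1.0, atol=atol):
            raise ValueError("every transition-matrix row must sum to 1")
        if not np.allclose(self.theta.sum(axis=0), 1.0, atol=atol):
            raise ValueError("every theta column must sum to 1")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=atol):
            raise ValueError("every initial distribution must sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_states": self.n_states,
            "A": self.A.tolist(),
            "theta": self.theta.tolist(),
            "pi": self.pi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OIMParams":
        return cls(A=np.array(d["A"]), theta=np.array(d["theta"]), pi=np.array(d["pi"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "OIMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitReport:
    """Diagnostics of an influence-weight fit.

    ``traces[c]`` is the per-iteration log-likelihood of the theta column of
    target chain ``c`` (non-decreasing by construction: only improving steps
    are accepted).
    """

    final_log_likelihood: float
    iterations: list = field(default_factory=list)
    traces: list = field(default_factory=list)
    uniform_rows: int = 0


def _check_labels(labels: np.ndarray, n_states: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 2:
        raise ValueError("labels must be a (C, R) array")
    if labels.size and (labels.min() < 1 or labels.max() > n_states):
        raise ValueError(f"labels must lie in 1..{n_states}")
    return labels


def count_transitions(labels: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Estimate transition matrices and initial distributions by counting.

    Parameters
    ----------
    labels : (C, R) int array with values in 1..n_states, R >= 2.

    Returns
    -------
    A : (C, C, N, N) row-stochastic count estimates; rows never observed are
        replaced by the uniform distribution (logged).
    pi : (C, N) empirical marginal state frequencies of each chain.
    uniform_rows : number of unobserved rows replaced by the uniform row.
    """
    labels = _check_labels(labels, n_states)
    C, R = labels.shape
    if R < 2:
        raise ValueError("need at least 2 synchronized segments to count transitions")
    N = n_states
    A = np.zeros((C, C, N, N))
    prev = labels[:, :-1] - 1
    nxt = labels[:, 1:] - 1
    for src in range(C):
        for tgt in range(C):
            np.add.at(A[src, tgt], (prev[src], nxt[tgt]), 1.0)
    row_sums = A.sum(axis=3, keepdims=True)
    empty = row_sums[..., 0] == 0
    n_uniform = int(empty.sum())
    if n_uniform:
        logger.debug("count_transitions: %d unobserved rows set to uniform", n_uniform)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(empty[..., None], 1.0 / N, A / np.where(row_sums == 0, 1.0, row_sums))
    pi = np.stack([np.bincount(labels[c] - 1, minlength=N) / R for c in range(C)])
    return A, pi, n_uniform


def _mixture_terms(labels: np.ndarray, A: np.ndarray, tgt: int) -> np.ndarray:
    """M[src, r] = A[src, tgt, labels[src, r]-1, labels[tgt, r+1]-1] for r=0..R-2."""
    C, R = labels.shape
    prev = labels - 1
    return np.stack([A[src, tgt, prev[src, :-1], prev[tgt, 1:]] for src in range(C)])


def log_likelihood(labels: np.ndarray, params: OIMParams) -> float:
    """Log-probability of synchronized label sequences under an OIM.

    Initial states contribute ``log pi``; every later step contributes, per
    chain, the log of the theta-weighted mixture of pairwise transition
    probabilities.  A required probability of exactly zero yields ``-inf``
    (a value, not an error, so ordering comparisons stay total).
    """
    labels = _check_labels(labels, params.n_states)
    C, R = labels.shape
    if C != params.n_chains:
        raise ValueError(f"labels have {C} chains but params have {params.n_chains}")
    with np.errstate(divide="ignore"):
        ll = float(np.sum(np.log(params.pi[np.arange(C), labels[:, 0] - 1])))
        if R >= 2:
            for c in range(C):
                M = _mixture_terms(labels, params.A, c)
                p = params.theta[:, c] @ M
                ll += float(np.log(p).sum())
    return ll


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, v.size + 1) > 0)[0][-1]
    tau = css[rho] / (rho + 1.0)
    return np.maximum(v - tau, 0.0)


def fit_influence(
    labels: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    init_theta: np.ndarray | None = None,
    step: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, FitReport]:
    """Fit the influence weights by projected gradient ascent.

    The transition matrices ``A`` and initial distributions ``pi`` are held
    fixed (they come from counting).  Each theta column is optimized
    independently: the per-chain objective sum_r log(theta . m_r) is concave
    on the simplex, so gradient ascent with Euclidean simplex projection and
    step halving on non-improvement converges to the maximum.  Iteration
    stops when the log-likelihood gain drops below ``tol`` or after
    ``max_iter`` accepted steps.
    """
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    C, N = A.shape[0], A.shape[2]
    labels = _check_labels(labels, N)
    if labels.shape[0] != C:
        raise ValueError("label chain count does not match A")
    R = labels.shape[1]
    if init_theta is None:
        init_theta = np.full((C, C), 1.0 / C)
    else:
        init_theta = np.asarray(init_theta, dtype=float)
        if init_theta.shape != (C, C):
            raise ValueError("init_theta must be C x C")
        if np.any(init_theta < 0) or not np.allclose(init_theta.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("init_theta columns must lie on the probability simplex")

    theta = np.empty((C, C))
    traces: list[list[float]] = []
    iters: list[int] = []
    for c in range(C):
        M = _mixture_terms(labels, A, c)  # (C, R-1)
        th = init_theta[:, c].copy()

        def objective(t: np.ndarray) -> float:
            with np.errstate(divide="ignore"):
                return float(np.log(t @ M).sum())

        cur = objective(th)
        if not np.isfinite(cur):
            raise ValueError("initial influence weights give zero likelihood")
        trace = [cur]
        st = step
        n_accept = 0
        scale = max(R - 1, 1)
        for _ in range(max_iter):
            p = th @ M
            grad = (M / p).sum(axis=1) / scale
            accepted = False
            while st >= 1e-12:
                cand = project_to_simplex(th + st * grad)
                val = objective(cand)
                if np.isfinite(val) and val > cur:
                    accepted = True
                    break
                st /= 2.0
            if not accepted:
                break
            gain = val - cur
            th, cur = cand, val
            trace.append(cur)
            n_accept += 1
            if gain < tol:
                break
        theta[:, c] = th
        traces.append(trace)
        iters.append(n_accept)

    params = OIMParams(A=A, theta=theta, pi=pi)
    report = FitReport(
        final_log_likelihood=log_likelihood(labels, params),
        iterations=iters,
        traces=traces,
    )
    return theta, report


def fit_oim(
    labels: np.ndarray,
    n_states: int,
    step: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[OIMParams, FitReport]:
    """Fit a full OIM to one dialog: counting, then influence-weight ascent."""
    A, pi, n_uniform = count_transitions(labels, n_states)
    theta, report = fit_influence(labels, A, pi, step=step, tol=tol, max_iter=max_iter)
    report.uniform_rows = n_uniform
    return OIMParams(A=A, theta=theta, pi=pi), report


def sample_labels(params: OIMParams, R: int, seed) -> np.ndarray:
    """Draw label sequences directly from the OIM transition law.

    This is the unconstrained model-level sampler: first states from
    ``pi``, each later state of each chain from the theta-weighted mixture
    of pairwise transition rows.  (The SCP-aware cohort generator, which
    additionally enforces that consecutive segments differ in speech or
    silence in at least one chain, lives in the synthetic module.)
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C, N = params.n_chains, params.n_states
    src_idx = np.arange(C)
    labels = np.empty((C, R), dtype=int)
    labels[:, 0] = [rng.choice(N, p=params.pi[c]) + 1 for c in range(C)]
    for r in range(1, R):
        prev0 = labels[:, r - 1] - 1
        for c in range(C):
            rows = params.A[src_idx, c, prev0, :]
            p = params.theta[:, c] @ rows
            labels[c, r] = rng.choice(N, p=p / p.sum()) + 1
    return labels


def best_ordering_score(labels: np.ndarray, params: OIMParams) -> tuple[float, int]:
    """Score a dyad under both chain orderings; return the best.

    With two chains the sequences can be presented to a fitted model in two
    orders; the correct classification score is the higher likelihood.
    Returns ``(log_likelihood, ordering)`` with ordering 0 for the original
    order and 1 for the swapped order; ties keep the original.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != 2 or params.n_chains != 2:
        raise ValueError("ordering search is defined for dyads (C=2)")
    ll0 = log_likelihood(labels, params)
    ll1 = log_likelihood(labels[::-1], params)
    if ll1 > ll0:
        return ll1, 1
    return ll0, 0
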