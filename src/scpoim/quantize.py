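"""Duration quantization: cluster SCP durations into scale classes.

SCP durations of each type (speech, silence) are clustered with a
one-dimensional Gaussian mixture fitted by EM, by default into k = 3
components (short / medium / long).  Each SCP is then labeled with one of
2k states: speech scales take labels 1..k, silence scales k+1..2k, so the
default configuration yields the 6-state alphabet used throughout.

EM runs through scikit-learn's GaussianMixture (k-means initialization,
variance floor 1e-6 s^2, tolerance 1e-6 on the per-sample log-likelihood,
at most 500 iterations), stepped one iteration at a time so the monotone
likelihood trace is available for diagnostics.  Decision boundaries between
adjacent components are the points of equal weighted component density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .signal import SCPSequence

logger = logging.getLogger(__name__)

__all__ = [
    "TypeClusters",
    "DurationClusters",
    "QuantizedDialog",
    "fit_duration_gmm",
    "assign_labels",
    "pool_durations",
]

TYPES = ("speech", "silence")


@dataclass
class TypeClusters:
    """One fitted 1-D mixture: components sorted by ascending mean.

    ``means``/``sds`` live in the fitted space (raw seconds, or log-seconds
    when ``log_space``); ``boundaries`` are always reported in seconds.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    boundaries: np.ndarray
    log_space: bool = False
    ll_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return int(self.means.size)

    def assign(self, durations: np.ndarray) -> np.ndarray:
        """Component of maximum responsibility (0-based).

        With components sorted by mean, ``argmax`` keeps the first maximum,
        so an exact responsibility tie resolves to the shorter-duration
        component.
        """
        x = np.atleast_1d(np.asarray(durations, dtype=float))
        if self.log_space:
            x = np.log(x)
        log_resp = (
            np.log(self.weights)[None, :]
            + stats.norm.logpdf(x[:, None], self.means[None, :], self.sds[None, :])
        )
        return np.argmax(log_resp, axis=1)


@dataclass
class DurationClusters:
    """Per-type duration mixtures plus the induced state alphabet size."""

    by_type: dict
    log_space: bool = False

    @property
    def n_scales(self) -> int:
        return self.by_type["speech"].k

    @property
    def n_states(self) -> int:
        return 2 * self.n_scales

    def to_dict(self) -> dict:
        return {
            "log_space": self.log_space,
            **{
                t: {
                    "means": c.means.tolist(),
                    "sds": c.sds.tolist(),
                    "weights": c.weights.tolist(),
                    "boundaries": c.boundaries.tolist(),
                }
                for t, c in self.by_type.items()
            },
        }


@dataclass
class QuantizedDialog:
    """Aligned per-chain label sequences over 1..2k for one dialog."""

    labels: np.ndarray
    n_states: int
    dialog_id: str = ""

    @property
    def R(self) -> int:
        return int(self.labels.shape[1])


def _fit_1d_gmm(x: np.ndarray, k: int, seed: int, tol: float, max_iter: int) -> TypeClusters:
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct duration values, got {np.unique(x).size}")
    X = x.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        tol=tol,
        max_iter=1,
        warm_start=True,
        init_params="kmeans",
        n_init=1,
        random_state=seed,
    )
    trace: list[float] = []
    prev = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            ll = float(gm.lower_bound_)
            trace.append(ll)
            if np.isfinite(prev) and ll - prev < tol:
                break
            prev = ll
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k))
    if np.any(gm.covariances_.reshape(k) <= 1.5e-6):
        logger.debug("duration GMM: variance at the 1e-6 floor for some component")
    weights = gm.weights_.copy()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    boundaries = np.empty(k - 1)
    for i in range(k - 1):
        m1, s1, w1 = means[i], sds[i], weights[i]
        m2, s2, w2 = means[i + 1], sds[i + 1], weights[i + 1]

        def f(z):
            return (np.log(w1) + stats.norm.logpdf(z, m1, s1)) - (
                np.log(w2) + stats.norm.logpdf(z, m2, s2)
            )

        if f(m1) > 0 > f(m2):
            boundaries[i] = optimize.brentq(f, m1, m2)
        else:  # one component dominates the whole interval
            logger.debug("duration GMM: no equal-density point between components, midpoint used")
            boundaries[i] = 0.5 * (m1 + m2)
    return TypeClusters(means=means, sds=sds, weights=weights, boundaries=boundaries, ll_trace=trace)


def fit_duration_gmm(
    durations: dict,
    k: int = 3,
    seed: int = 0,
    log_space: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> DurationClusters:
    """Fit per-type duration mixtures.

    Parameters
    ----------
    durations : mapping with keys 'speech' and 'silence' to arrays of
        positive segment durations in seconds (pooled over whichever
        dialogs/chains the caller chooses — training folds only, in a
        cross-validation setting).
    log_space : cluster log-durations instead of raw durations.  The raw
        scale is the default; boundaries are always reported in seconds.
    """
    by_type = {}
    for i, t in enumerate(TYPES):
        if t not in durations:
            raise ValueError(f"durations must contain key '{t}'")
        x = np.asarray(durations[t], dtype=float)
        if np.any(x <= 0):
            raise ValueError("durations must be strictly positive")
        fitted = _fit_1d_gmm(np.log(x) if log_space else x, k, seed + i, tol, max_iter)
        if log_space:
            fitted.log_space = True
            fitted.boundaries = np.exp(fitted.boundaries)
        by_type[t] = fitted
    return DurationClusters(by_type=by_type, log_space=log_space)


def assign_labels(scps: SCPSequence, clusters: DurationClusters) -> QuantizedDialog:
    """Label every SCP of both chains with a state in 1..2k.

    Speech segments map to the speech mixture's component + 1, silence
    segments to k + component + 1, so label type always matches the chain's
    binary state and relabeling with the same clusters is idempotent.
    """
    k = clusters.n_scales
    durations = scps.durations
    comp = {t: clusters.by_type[t].assign(durations) for t in TYPES}
    labels = np.where(scps.states == 1, comp["speech"][None, :] + 1, comp["silence"][None, :] + 1 + k)
    return QuantizedDialog(labels=labels.astype(int), n_states=2 * k, dialog_id=scps.dialog_id)


def pool_durations(scp_list: list) -> dict:
    """Pool speech and silence durations over dialogs and both chains."""
    speech, silence = [], []
    for scps in scp_list:
        d = scps.durations
        for c in range(scps.states.shape[0]):
            speech.append(d[scps.states[c] == 1])
            silence.append(d[scps.states[c] == 0])
    return {
        "speech": np.concatenate(speech) if speech else np.empty(0),
        "silence": np.concatenate(silence) if silence else np.empty(0),
    }
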