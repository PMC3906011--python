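"""Study conditions and end-to-end simulation experiments.

This module pins down the synthetic study design used throughout the
analysis scripts, the tests and the acceptance script:

* a dyadic base OIM (N = 6, C = 2) with turn-taking-flavored dynamics —
  after a speech state a chain preferentially moves to a silence scale and
  vice versa, which is both conversationally realistic and keeps the
  fraction of draws in which neither chain changes speech/silence type
  (rejected by the SCP sampler) small;
* asymmetric influence: the moderator is largely self-driven
  (theta_11 = 0.7) while the participant is driven by the moderator
  (theta_12 = 0.6);
* log-normal segment durations on three well-separated scales per type
  (speech medians 0.4 / 2.5 / 8.0 s, silence 0.3 / 2.0 / 7.0 s,
  sigma = 0.2), giving dialogs of several minutes at the default 150
  segments;
* a "planted" case class identical to the base except that 0.3 of
  probability mass in the moderator's intra-chain medium-silence row moves
  from the short-speech target to the long-speech target — exactly two
  score-space features (positions 5 and 17) differ between classes;
* cohorts of 9 + 9 dialogs, mirroring the two groups of nine participants.

The leave-one-out evaluation here is fold-nested: each fold re-runs the
full stability ranking on its training samples only, so a null cohort
(identical class models) scores at chance instead of inheriting the
optimism of features selected on the complete sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import EvaluationReport, loo_evaluate, _metrics, _predict
from .oim import OIMParams, fit_oim
from .quantize import assign_labels, fit_duration_gmm, pool_durations
from .scorespace import embed_cohort
from .selection import DEFAULT_POLICIES, stability_rank
from .signal import extract_scps
from .synthetic import ClassSpec, Cohort, generate_cohort, lognormal_duration_models

__all__ = [
    "base_influence_model",
    "planted_influence_model",
    "recovery_influence_model",
    "default_duration_models",
    "make_cohort_specs",
    "cohort_feature_matrix",
    "nested_loo_evaluate",
    "power_study",
    "PLANTED_FEATURES",
]

# 1-based score-vector positions that differ between the two classes:
# A^(11) medium silence -> short speech (5) and medium silence -> long
# speech (17).
PLANTED_FEATURES = (5, 17)

_A11 = np.array(
    [
        [0.05, 0.05, 0.02, 0.45, 0.28, 0.15],
        [0.04, 0.04, 0.02, 0.25, 0.40, 0.25],
        [0.03, 0.04, 0.03, 0.15, 0.30, 0.45],
        [0.40, 0.30, 0.12, 0.06, 0.07, 0.05],
        [0.40, 0.22, 0.08, 0.12, 0.08, 0.10],
        [0.20, 0.30, 0.32, 0.06, 0.06, 0.06],
    ]
)
_A22 = np.array(
    [
        [0.06, 0.06, 0.03, 0.40, 0.30, 0.15],
        [0.05, 0.05, 0.02, 0.20, 0.38, 0.30],
        [0.04, 0.04, 0.04, 0.12, 0.28, 0.48],
        [0.45, 0.25, 0.10, 0.07, 0.08, 0.05],
        [0.30, 0.35, 0.10, 0.08, 0.09, 0.08],
        [0.25, 0.28, 0.27, 0.07, 0.07, 0.06],
    ]
)
_A12 = np.array(
    [
        [0.08, 0.07, 0.05, 0.35, 0.30, 0.15],
        [0.06, 0.06, 0.03, 0.30, 0.35, 0.20],
        [0.05, 0.05, 0.05, 0.20, 0.30, 0.35],
        [0.38, 0.27, 0.10, 0.08, 0.09, 0.08],
        [0.30, 0.30, 0.15, 0.08, 0.09, 0.08],
        [0.22, 0.28, 0.25, 0.08, 0.09, 0.08],
    ]
)
_A21 = np.array(
    [
        [0.07, 0.08, 0.05, 0.33, 0.32, 0.15],
        [0.05, 0.07, 0.03, 0.28, 0.36, 0.21],
        [0.04, 0.06, 0.05, 0.18, 0.32, 0.35],
        [0.40, 0.26, 0.11, 0.08, 0.08, 0.07],
        [0.32, 0.28, 0.14, 0.09, 0.09, 0.08],
        [0.24, 0.27, 0.24, 0.08, 0.09, 0.08],
    ]
)


def base_influence_model() -> OIMParams:
    """Ground-truth dyadic OIM for the control class (N = 6, C = 2)."""
    A = np.stack(
        [np.stack([_A11, _A12]), np.stack([_A21, _A22])]
    )  # A[src, tgt]
    theta = np.array([[0.7, 0.6], [0.3, 0.4]])  # theta[src, tgt]
    pi = np.array(
        [
            [0.25, 0.10, 0.05, 0.35, 0.15, 0.10],
            [0.20, 0.10, 0.05, 0.40, 0.15, 0.10],
        ]
    )
    return OIMParams(A=A, theta=theta, pi=pi)


def planted_influence_model(effect: float = 0.3) -> OIMParams:
    """Case-class OIM: base model with one transition cell shifted.

    ``effect`` of probability mass moves within the moderator's intra-chain
    medium-silence row from the short-speech to the long-speech target, so
    exactly two transition cells (score positions 5 and 17) differ from the
    base model, each by ``effect``.
    """
    base = base_influence_model()
    A = base.A.copy()
    A[0, 0, 4, 0] -= effect
    A[0, 0, 4, 2] += effect
    if A[0, 0, 4, 0] < 0 or A[0, 0, 4, 2] > 1:
        raise ValueError("effect size leaves the probability simplex")
    return OIMParams(A=A, theta=base.theta.copy(), pi=base.pi.copy())


def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    vec = np.abs(vec)
    return vec / vec.sum()


def recovery_influence_model() -> OIMParams:
    """A self-consistent OIM for parameter-recovery simulations.

    State counting estimates the pairwise conditionals of the joint
    process; those coincide with the model's own matrices only when the
    model is self-consistent.  This construction guarantees it: identity
    influence (each chain driven by its own intra matrix), inter-chain
    matrices equal to the stationary one-step marginals they induce
    (row-constant), and stationary initial distributions.  Sampling from
    this model and re-estimating recovers every parameter up to sampling
    noise, which is what the recovery checks quantify.
    """
    stat1 = _stationary(_A11)
    stat2 = _stationary(_A22)
    A12 = np.tile(stat2 @ _A22, (6, 1))
    A21 = np.tile(stat1 @ _A11, (6, 1))
    A = np.stack([np.stack([_A11, A12]), np.stack([A21, _A22])])
    theta = np.eye(2)
    pi = np.stack([stat1, stat2])
    return OIMParams(A=A, theta=theta, pi=pi)


def default_duration_models() -> dict:
    """Log-normal segment durations on three separated scales per type.

    Adjacent scale medians differ by a factor of 5-6 with log-sd 0.2, which
    keeps the three clumps resolvable by the raw-scale 3-component EM the
    quantizer uses (the scales must be separable in seconds, not only in
    log-seconds, for the short/medium/long labels to be recoverable).
    """
    return lognormal_duration_models(
        {
            1: (0.4, 0.2),  # short speech
            2: (2.5, 0.2),  # medium speech
            3: (8.0, 0.2),  # long speech
            4: (0.3, 0.2),  # short silence
            5: (2.0, 0.2),  # medium silence
            6: (7.0, 0.2),  # long silence
        }
    )


def make_cohort_specs(
    effect: float = 0.3,
    n_dialogs: int = 9,
    dialog_length: int = 150,
) -> list:
    """Control and case class specs; ``effect=0`` gives a null cohort."""
    models = default_duration_models()
    control = ClassSpec(
        name="control",
        oim=base_influence_model(),
        duration_models=models,
        dialog_length=dialog_length,
        n_dialogs=n_dialogs,
    )
    case = ClassSpec(
        name="case",
        oim=planted_influence_model(effect) if effect else base_influence_model(),
        duration_models=models,
        dialog_length=dialog_length,
        n_dialogs=n_dialogs,
    )
    return [control, case]


def cohort_feature_matrix(
    cohort: Cohort,
    n_scales: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run a cohort through SCP extraction, quantization, OIM fitting and
    embedding; returns (score matrix, class labels, artifacts).

    The duration quantizer is fitted once on the pooled durations of all
    dialogs and both chains.  In the synthetic design both classes share
    the duration models, so the quantizer carries no class information.
    """
    scps = [extract_scps(d.dyad, dialog_id=d.participant_id) for d in cohort.dialogs]
    clusters = fit_duration_gmm(pool_durations(scps), k=n_scales, seed=seed)
    quantized = [assign_labels(s, clusters) for s in scps]
    fits = [fit_oim(q.labels, n_states=2 * n_scales) for q in quantized]
    params = [p for p, _ in fits]
    X, headers = embed_cohort(params)
    y = cohort.class_names
    artifacts = {
        "scps": scps,
        "clusters": clusters,
        "quantized": quantized,
        "params": params,
        "reports": [r for _, r in fits],
        "headers": headers,
    }
    return X, y, artifacts


def nested_loo_evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 2,
    T: int = 10,
    policies=DEFAULT_POLICIES,
    classifier: str = "knn",
    K: int = 3,
    svm_C: float = 100.0,
) -> tuple[EvaluationReport, list]:
    """Leave-one-out evaluation with per-fold feature ranking.

    For every fold the full stability ranking (all policies, inner LOO) is
    recomputed on the n-1 training samples; the held-out sample is
    classified on that fold's top-k features.  Returns the pooled report
    and the per-fold top-k feature lists (0-based indices).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    classes = tuple(np.unique(y))
    pred = np.empty(n, dtype=y.dtype)
    fold_features = []
    for i in range(n):
        mask = np.arange(n) != i
        ranking = stability_rank(X[mask], y[mask], policies=policies, T=T)
        top = ranking.order[:k]
        fold_features.append(top)
        pred[i] = _predict(classifier, X[mask][:, top], y[mask], X[i, top], K, svm_C)[0]
    precision, recall, mean_recall = _metrics(y, pred, classes)
    report = EvaluationReport(
        classifier=classifier,
        mode="loo-nested",
        classes=classes,
        precision=precision,
        recall=recall,
        mean_recall=mean_recall,
        predictions=pred,
        true_labels=y,
    )
    return report, fold_features


@dataclass
class ReplicateResult:
    """Everything one simulated cohort produced."""

    seed_key: tuple
    scores: np.ndarray
    labels: np.ndarray
    nested_mean_recall: float
    pooled_order: list
    fold_features: list = field(default_factory=list)


def power_study(
    n_replicates: int = 20,
    effect: float = 0.3,
    base_seed: int = 0,
    n_dialogs: int = 9,
    dialog_length: int = 150,
    k: int = 2,
    T: int = 10,
    policies=DEFAULT_POLICIES,
    classifier: str = "knn",
) -> list:
    """Repeat the full planted-effect (or null) pipeline over fresh cohorts.

    Every replicate simulates a 9+9 cohort, runs SCP extraction through
    embedding, computes the pooled stability ranking (the interpretive
    Table-style artifact) and the fold-nested LOO mean recall on the top-k
    features.  Seeds derive from ``base_seed`` and the replicate index.
    """
    results = []
    specs = make_cohort_specs(effect=effect, n_dialogs=n_dialogs, dialog_length=dialog_length)
    for rep in range(n_replicates):
        key = (base_seed, 1 if effect else 0, rep)
        cohort = generate_cohort(specs, np.random.SeedSequence(key))
        gmm_seed = int(np.random.SeedSequence(key + (7,)).generate_state(1)[0] % (2**31))
        X, y, _ = cohort_feature_matrix(cohort, seed=gmm_seed)
        report, fold_features = nested_loo_evaluate(
            X, y, k=k, T=T, policies=policies, classifier=classifier
        )
        pooled = stability_rank(X, y, policies=policies, T=T)
        results.append(
            ReplicateResult(
                seed_key=key,
                scores=X,
                labels=y,
                nested_mean_recall=report.mean_recall,
                pooled_order=pooled.order,
                fold_features=fold_features,
            )
        )
    return results
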