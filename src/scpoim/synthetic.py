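"""Synthetic two-class cohorts of dyadic dialogs with known ground truth.

Real clinical recordings cannot be redistributed, so every downstream stage
of the pipeline is exercised on simulated dyads whose SCP label dynamics
follow class-specific observed influence models.  Each dialog is drawn in
label space from its class OIM (N = 6 states: short/medium/long speech and
short/medium/long silence), segment durations are drawn from per-label
positive distributions on three separated scales, and the labels are then
rendered to synchronized binary sample streams.

The label sampler enforces the defining SCP property that every boundary is
a change of speech/silence state in at least one chain: a drawn joint state
whose two chains both keep their speech/silence *type* would be invisible
in the rendered binary signal, so it is resampled (up to a retry budget)
and otherwise merged with its predecessor and logged.  This keeps the
render -> extract round trip exact on boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .oim import OIMParams
from .signal import BinaryDyad

logger = logging.getLogger(__name__)

__all__ = [
    "ClassSpec",
    "DialogRecord",
    "Cohort",
    "state_is_speech",
    "lognormal_duration_models",
    "sample_joint_labels",
    "render_binary_dyad",
    "generate_cohort",
]


def state_is_speech(labels: np.ndarray, n_states: int) -> np.ndarray:
    """Labels 1..N/2 are speech scales, N/2+1..N silence scales."""
    return np.asarray(labels) <= n_states // 2


def lognormal_duration_models(median_sigma: dict[int, tuple[float, float]]):
    """Build frozen log-normal duration distributions from (median s, sigma)."""
    from scipy import stats

    return {
        label: stats.lognorm(s=sigma, scale=median)
        for label, (median, sigma) in median_sigma.items()
    }


@dataclass
class ClassSpec:
    """Ground truth for one class of dialogs.

    ``duration_models`` maps each state label (1..N) to a frozen positive
    continuous distribution of segment durations in seconds; scale means
    must increase within the speech labels and within the silence labels.
    """

    name: str
    oim: OIMParams
    duration_models: dict
    dialog_length: int = 150
    n_dialogs: int = 9

    def __post_init__(self) -> None:
        self.oim.validate()
        N = self.oim.n_states
        if self.dialog_length < 1:
            raise ValueError("dialog_length must be >= 1")
        if self.n_dialogs < 1:
            raise ValueError("n_dialogs must be >= 1")
        if set(self.duration_models) != set(range(1, N + 1)):
            raise ValueError(f"duration_models must cover labels 1..{N}")
        means = {}
        for label, dist in self.duration_models.items():
            lo, _ = dist.support()
            if lo < 0:
                raise ValueError("duration distributions must have positive support")
            means[label] = float(dist.mean())
        half = N // 2
        for group in (range(1, half + 1), range(half + 1, N + 1)):
            g = [means[l] for l in group]
            if not all(a < b for a, b in zip(g, g[1:])):
                raise ValueError(
                    "duration means must increase strictly within speech and within silence"
                )


@dataclass
class DialogRecord:
    """One simulated dialog with its generating ground truth."""

    dyad: BinaryDyad
    class_name: str
    participant_id: str
    true_labels: np.ndarray
    truncated: bool = False
    merge_events: int = 0


@dataclass
class Cohort:
    dialogs: list
    seed: object
    specs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.dialogs)

    @property
    def class_names(self) -> np.ndarray:
        return np.array([d.class_name for d in self.dialogs])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_joint_labels(
    oim: OIMParams,
    R: int,
    seed,
    max_retries: int = 100,
    max_consecutive_merges: int = 50,
) -> tuple[np.ndarray, dict]:
    """Draw a pair of synchronized label sequences from an OIM.

    First states come from ``pi`` per chain; each subsequent joint state is
    drawn chainwise from the theta-weighted mixture of pairwise transition
    rows.  A draw in which both chains keep their speech/silence type is
    resampled up to ``max_retries`` times; if it persists it is merged with
    its predecessor (counted in the metadata), and after
    ``max_consecutive_merges`` consecutive merges generation stops early
    with the ``truncated`` flag set (degenerate absorbing dynamics).

    Returns ``(labels, info)`` with ``labels`` of shape (C, R') for
    R' <= R post-merge segments and ``info`` carrying ``truncated`` and
    ``merge_events``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    oim.validate()
    rng = _as_rng(seed)
    C, N = oim.n_chains, oim.n_states
    half = N // 2
    src_idx = np.arange(C)

    prev = np.array([rng.choice(N, p=oim.pi[c]) + 1 for c in range(C)])
    out = [prev]
    merges = 0
    consecutive = 0
    truncated = False
    while len(out) < R:
        prev0 = prev - 1
        accepted = None
        for _ in range(max_retries + 1):
            nxt = np.empty(C, dtype=int)
            for c in range(C):
                rows = oim.A[src_idx, c, prev0, :]  # (C, N)
                p = oim.theta[:, c] @ rows
                nxt[c] = rng.choice(N, p=p / p.sum()) + 1
            if C > 1 and np.all((nxt <= half) == (prev <= half)):
                continue  # both chains kept their type: not a global transition
            accepted = nxt
            break
        if accepted is None:
            merges += 1
            consecutive += 1
            if consecutive >= max_consecutive_merges:
                truncated = True
                logger.warning(
                    "sample_joint_labels: absorbing dynamics, stopping at %d of %d segments",
                    len(out),
                    R,
                )
                break
        else:
            out.append(accepted)
            prev = accepted
            consecutive = 0
    labels = np.stack(out, axis=1)
    return labels, {"truncated": truncated, "merge_events": merges}


def render_binary_dyad(
    labels: np.ndarray,
    duration_models: dict,
    sample_rate: float,
    seed,
) -> BinaryDyad:
    """Render synchronized label sequences into binary sample streams.

    SCP boundaries are global, so each segment gets a single duration shared
    by both chains, drawn from the duration model of chain 1's label.  Each
    chain's samples within a segment are 1 when its label is a speech scale
    and 0 otherwise.  Segments whose rounded length would be zero samples
    are given one sample and logged.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 2:
        raise ValueError("labels must be a (C, R) array")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    C, R = labels.shape
    n_states = 2 * (max(duration_models) // 2)
    rng = _as_rng(seed)

    durations = np.empty(R)
    for label in np.unique(labels[0]):
        idx = np.nonzero(labels[0] == label)[0]
        durations[idx] = np.atleast_1d(
            duration_models[int(label)].rvs(size=idx.size, random_state=rng)
        )
    n_samples = np.round(durations * sample_rate).astype(int)
    n_zero = int(np.sum(n_samples < 1))
    if n_zero:
        logger.debug("render_binary_dyad: %d zero-length segments floored to 1 sample", n_zero)
    n_samples = np.maximum(n_samples, 1)

    streams = [
        np.repeat(state_is_speech(labels[c], max(labels.max(), n_states)).astype(np.uint8), n_samples)
        for c in range(C)
    ]
    return BinaryDyad(y1=streams[0], y2=streams[1], sample_rate=sample_rate)


def generate_cohort(
    specs: list,
    seed,
    sample_rate: float = 100.0,
) -> Cohort:
    """Sample a full cohort: per-class dialogs with derived per-dialog seeds.

    Per-dialog random streams are spawned from a single
    ``numpy.random.SeedSequence`` rooted at ``seed`` (one child per dialog,
    in class-then-dialog order), so the cohort is reproduced exactly from
    the cohort seed alone.
    """
    if not specs:
        raise ValueError("need at least one class spec")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    total = sum(s.n_dialogs for s in specs)
    children = root.spawn(total)
    dialogs = []
    k = 0
    for spec in specs:
        for d in range(spec.n_dialogs):
            rng = np.random.default_rng(children[k])
            k += 1
            labels, info = sample_joint_labels(spec.oim, spec.dialog_length, rng)
            dyad = render_binary_dyad(labels, spec.duration_models, sample_rate, rng)
            dialogs.append(
                DialogRecord(
                    dyad=dyad,
                    class_name=spec.name,
                    participant_id=f"{spec.name}_{d + 1:02d}",
                    true_labels=labels,
                    truncated=info["truncated"],
                    merge_events=info["merge_events"],
                )
            )
    return Cohort(dialogs=dialogs, seed=seed, specs=list(specs))
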