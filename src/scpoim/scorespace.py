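"""Generative score space: a fitted OIM's parameters as a feature vector.

Each dialog is represented by the parameters of the OIM trained on it: the
parameter-extractor function plays the role of the score map, the operator
applied afterwards is the identity, and distances in the space are
Euclidean.  For N = 6 states and C = 2 chains the vector has
C^2 N^2 + C^2 + C N = 160 entries.

Canonical index scheme (1-based positions):

* positions 1..144 — the four transition matrices in the order
  A^(11), A^(12), A^(21), A^(22) (source chain, target chain; chain 1 is
  the moderator), each flattened column-major, i.e. within a matrix the
  linear index is (to_state - 1) * N + from_state;
* positions 145..148 — the influence matrix, column-major
  (theta_11, theta_21, theta_12, theta_22);
* positions 149..160 — the initial distributions pi^1 then pi^2.

Under this convention position 17 is the moderator's intra-chain
probability of a long speech segment after a medium silence, and position
80 is the inter-chain probability that the moderator speaks for a medium
interval after the participant has spoken for a medium-length segment;
``describe_feature`` renders these readings for any position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oim import OIMParams

__all__ = [
    "FeatureDescriptor",
    "ScoreVector",
    "score_length",
    "embed_dialog",
    "embed_cohort",
    "feature_descriptor",
    "describe_feature",
    "state_name",
]

CHAIN_NAMES = {1: "moderator", 2: "participant"}
_SCALES = {1: ("",), 2: ("short", "long"), 3: ("short", "medium", "long")}


def score_length(n_states: int, n_chains: int = 2) -> int:
    """C^2 N^2 + C^2 + C N."""
    return n_chains**2 * n_states**2 + n_chains**2 + n_chains * n_states


def state_name(state: int, n_states: int) -> str:
    """Human-readable name of a state label, e.g. 5 -> 'medium silence'."""
    half = n_states // 2
    if not 1 <= state <= n_states:
        raise ValueError(f"state must lie in 1..{n_states}")
    kind = "speech" if state <= half else "silence"
    scale = _SCALES[half][(state - 1) % half]
    return f"{scale} {kind}".strip()


@dataclass(frozen=True)
class FeatureDescriptor:
    """Structured meaning of one score-vector position."""

    block: str  # 'transition' | 'influence' | 'initial'
    source_chain: int
    target_chain: int
    from_state: int | None = None
    to_state: int | None = None


def feature_descriptor(index: int, n_states: int = 6, n_chains: int = 2) -> FeatureDescriptor:
    """Decode a 1-based score-vector position into its parameter."""
    N, C = n_states, n_chains
    L = score_length(N, C)
    if not 1 <= index <= L:
        raise ValueError(f"index must lie in 1..{L}")
    i = index - 1
    n_trans = C * C * N * N
    if i < n_trans:
        m, w = divmod(i, N * N)
        src, tgt = divmod(m, C)
        to, frm = divmod(w, N)
        return FeatureDescriptor(
            block="transition",
            source_chain=src + 1,
            target_chain=tgt + 1,
            from_state=frm + 1,
            to_state=to + 1,
        )
    i -= n_trans
    if i < C * C:
        tgt, src = divmod(i, C)  # column-major theta
        return FeatureDescriptor(block="influence", source_chain=src + 1, target_chain=tgt + 1)
    i -= C * C
    chain, state = divmod(i, N)
    return FeatureDescriptor(
        block="initial", source_chain=chain + 1, target_chain=chain + 1, from_state=state + 1
    )


def describe_feature(index: int, n_states: int = 6, n_chains: int = 2) -> str:
    """Deterministic human-readable description of one position."""
    d = feature_descriptor(index, n_states, n_chains)
    src = CHAIN_NAMES.get(d.source_chain, f"chain {d.source_chain}")
    tgt = CHAIN_NAMES.get(d.target_chain, f"chain {d.target_chain}")
    if d.block == "transition":
        kind = "intra-chain" if d.source_chain == d.target_chain else "inter-chain"
        return (
            f"{kind} A^({d.source_chain}{d.target_chain}): "
            f"P({tgt} {state_name(d.to_state, n_states)} after "
            f"{src} {state_name(d.from_state, n_states)})"
        )
    if d.block == "influence":
        return f"influence theta_{d.source_chain}{d.target_chain}: {src} on {tgt}"
    return f"initial pi^{d.source_chain}: P({src} starts in {state_name(d.from_state, n_states)})"


@dataclass
class ScoreVector:
    """Fixed-length parameter embedding of one dialog; metric is Euclidean."""

    values: np.ndarray
    n_states: int
    n_chains: int = 2
    dialog_id: str = ""

    def __len__(self) -> int:
        return int(self.values.size)

    def descriptor(self, index: int) -> FeatureDescriptor:
        return feature_descriptor(index, self.n_states, self.n_chains)


def embed_dialog(params: OIMParams, dialog_id: str = "") -> ScoreVector:
    """Map a fitted OIM to its canonical score vector."""
    C, N = params.n_chains, params.n_states
    blocks = [params.A[s, t].T.ravel() for s in range(C) for t in range(C)]
    blocks.append(params.theta.ravel(order="F"))
    blocks.extend(params.pi[c] for c in range(C))
    values = np.concatenate(blocks)
    assert values.size == score_length(N, C)
    return ScoreVector(values=values, n_states=N, n_chains=C, dialog_id=dialog_id)


def embed_cohort(params_list: list, n_states: int | None = None) -> tuple[np.ndarray, list]:
    """Stack dialog embeddings into a (n_dialogs, L) matrix with headers."""
    vecs = [embed_dialog(p) for p in params_list]
    if not vecs:
        raise ValueError("params_list is empty")
    N, C = vecs[0].n_states, vecs[0].n_chains
    if n_states is not None and N != n_states:
        raise ValueError("model state count does not match requested n_states")
    headers = [describe_feature(i, N, C) for i in range(1, score_length(N, C) + 1)]
    return np.stack([v.values for v in vecs]), headers
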