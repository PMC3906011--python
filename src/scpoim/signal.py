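"""Binary speech/silence dyads and Steady Conversational Period extraction.

A dyadic conversation is represented by two synchronized binary sample
streams (1 = speech, 0 = silence), one per interactant.  A Steady
Conversational Period (SCP) is a segment between consecutive *global*
transitions: whenever either speaker's stream changes state, the boundary
cuts both streams, so after extraction both chains share all segment
boundaries and hold one constant state per segment.  This synchronization
is what makes first-order inter-chain transition statistics well defined.

Chain identity is fixed throughout the package: chain 1 is the moderator,
chain 2 the participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryDyad",
    "SCPSequence",
    "extract_scps",
    "speech_silence_fractions",
    "binarize_audio",
]


@dataclass
class BinaryDyad:
    """Two equal-length binary sample arrays plus their sample rate.

    Segments are addressed with 0-based, half-open ``[start, end)`` sample
    coordinates; durations are reported in seconds.
    """

    y1: np.ndarray
    y2: np.ndarray
    sample_rate: float
    ids: tuple[str, str] = ("moderator", "participant")

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=np.uint8)
        self.y2 = np.asarray(self.y2, dtype=np.uint8)
        if self.y1.ndim != 1 or self.y2.ndim != 1:
            raise ValueError("dyad streams must be 1-D")
        if self.y1.size != self.y2.size:
            raise ValueError("dyad streams must have equal length")
        if self.y1.size < 1:
            raise ValueError("dyad streams must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for y in (self.y1, self.y2):
            if np.any((y != 0) & (y != 1)):
                raise ValueError("dyad streams must be 0/1 valued")

    @property
    def n_samples(self) -> int:
        return int(self.y1.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class SCPSequence:
    """Synchronized segments shared by both chains of a dyad.

    ``boundaries`` holds R+1 strictly increasing sample indices with
    ``boundaries[0] == 0`` and ``boundaries[-1] == T``; segment r spans
    ``[boundaries[r], boundaries[r+1])``.  ``states[c, r]`` is 1 when chain
    c speaks throughout segment r, 0 when silent.
    """

    boundaries: np.ndarray
    states: np.ndarray
    sample_rate: float
    ids: tuple[str, str] = ("moderator", "participant")
    dialog_id: str = ""

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.uint8)

    @property
    def R(self) -> int:
        return int(self.boundaries.size - 1)

    @property
    def durations(self) -> np.ndarray:
        """Per-segment durations in seconds (shared by both chains)."""
        return np.diff(self.boundaries) / self.sample_rate


def extract_scps(dyad: BinaryDyad, dialog_id: str = "") -> SCPSequence:
    """Cut a dyad at every change point of either stream.

    The boundary set is ``{0, T}`` united with the change points of both
    chains, so the number of internal boundaries equals the size of the
    union of the two chains' change-point sets and both chains end up with
    the same segment count R.  A constant dyad yields R = 1.
    """
    y = np.stack([dyad.y1, dyad.y2])
    change = np.nonzero((y[:, 1:] != y[:, :-1]).any(axis=0))[0] + 1
    boundaries = np.concatenate([[0], change, [dyad.n_samples]])
    states = y[:, boundaries[:-1]]
    return SCPSequence(
        boundaries=boundaries,
        states=states,
        sample_rate=dyad.sample_rate,
        ids=dyad.ids,
        dialog_id=dialog_id,
    )


def speech_silence_fractions(dyad: BinaryDyad) -> dict[str, tuple[float, float]]:
    """Per-chain (speech, silence) sample fractions; each pair sums to one."""
    out = {}
    for name, y in zip(dyad.ids, (dyad.y1, dyad.y2)):
        speech = float(np.mean(y))
        out[name] = (speech, 1.0 - speech)
    return out


def binarize_audio(
    waveform: np.ndarray,
    sample_rate: float,
    frame_ms: float = 20.0,
    energy_threshold: float = 0.01,
    min_segment_ms: float = 100.0,
) -> np.ndarray:
    """Threshold a mono waveform into a per-sample 0/1 speech stream.

    Frame RMS energy is compared against ``energy_threshold``; runs of
    frames shorter than ``min_segment_ms`` are merged into their neighbors
    (shortest run first, earlier run on ties); the frame decisions are then
    expanded back to one value per input sample.  This is deliberately
    simple, configurable plumbing — any external voice-activity detector
    can be substituted upstream.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("waveform is empty")
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    if energy_threshold < 0:
        raise ValueError("energy_threshold must be nonnegative")
    frame_len = max(1, int(round(frame_ms * sample_rate / 1000.0)))
    n_frames = int(np.ceil(waveform.size / frame_len))
    padded = np.zeros(n_frames * frame_len)
    padded[: waveform.size] = waveform
    rms = np.sqrt((padded.reshape(n_frames, frame_len) ** 2).mean(axis=1))
    b = (rms > energy_threshold).astype(np.uint8)

    min_frames = int(np.ceil(min_segment_ms / frame_ms))
    while True:
        starts = np.concatenate([[0], np.nonzero(b[1:] != b[:-1])[0] + 1])
        lengths = np.diff(np.concatenate([starts, [b.size]]))
        if starts.size <= 1:
            break
        short = np.nonzero(lengths < min_frames)[0]
        if short.size == 0:
            break
        k = short[np.argmin(lengths[short])]
        s, l = starts[k], lengths[k]
        b[s : s + l] = 1 - b[s]  # flip the run, merging it with its neighbors
    return np.repeat(b, frame_len)[: waveform.size]
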