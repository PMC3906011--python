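"""Reading and writing the pipeline's plain-text artifacts.

Dialogs travel as two-column delimited text of 0/1 samples (one column per
speaker) with a JSON sidecar carrying the sample rate, class label and any
ground-truth provenance; models, clusters and rankings are JSON.  WAV
input, when used, is read with scipy and binarized upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .signal import BinaryDyad

__all__ = [
    "save_dyad_text",
    "load_dyad_text",
    "load_wav",
    "dump_json",
    "load_json",
]


def save_dyad_text(dyad: BinaryDyad, path, sidecar: dict | None = None) -> None:
    """Write a dyad as two tab-separated 0/1 columns (+ optional sidecar)."""
    path = Path(path)
    np.savetxt(path, np.column_stack([dyad.y1, dyad.y2]), fmt="%d", delimiter="\t")
    meta = {"sample_rate": dyad.sample_rate, "ids": list(dyad.ids)}
    if sidecar:
        meta.update(sidecar)
    dump_json(meta, path.with_suffix(path.suffix + ".json"))


def load_dyad_text(path, sample_rate: float | None = None) -> BinaryDyad:
    """Read a two-column 0/1 dialog; sample rate from the sidecar if present."""
    path = Path(path)
    data = np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"expected two columns in {path}, got {data.shape[1]}")
    sidecar = path.with_suffix(path.suffix + ".json")
    ids = ("moderator", "participant")
    if sidecar.exists():
        meta = load_json(sidecar)
        sample_rate = sample_rate or meta.get("sample_rate")
        ids = tuple(meta.get("ids", ids))
    if sample_rate is None:
        raise ValueError("sample_rate not given and no sidecar found")
    return BinaryDyad(y1=data[:, 0], y2=data[:, 1], sample_rate=float(sample_rate), ids=ids)


def load_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file as float samples in [-1, 1] plus its rate."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def dump_json(obj, path) -> None:
    """Canonical JSON writing: sorted keys, no timestamps, stable floats."""
    with open(path, "w") as fh:
        json.dump(_to_plain(obj), fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
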