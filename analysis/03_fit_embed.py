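#!/usr/bin/env python
"""Fit one observed influence model per dialog and embed the cohort.

Each dialog's quantized SCP label pair yields a 160-parameter OIM
(transition matrices by counting, influence weights by projected gradient
ascent); the parameter vectors form the generative score space.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scpoim.io import load_dyad_text, load_json
from scpoim.oim import fit_oim
from scpoim.quantize import DurationClusters, TypeClusters, assign_labels
from scpoim.scorespace import embed_cohort
from scpoim.signal import extract_scps

import numpy as np

BASE = Path(__file__).resolve().parents[1] / "results" / "demo"


def load_clusters() -> DurationClusters:
    raw = load_json(BASE / "clusters.json")["clusters"]
    by_type = {
        t: TypeClusters(
            means=np.array(raw[t]["means"]),
            sds=np.array(raw[t]["sds"]),
            weights=np.array(raw[t]["weights"]),
            boundaries=np.array(raw[t]["boundaries"]),
        )
        for t in ("speech", "silence")
    }
    return DurationClusters(by_type=by_type, log_space=raw.get("log_space", False))


def main() -> None:
    clusters = load_clusters()
    params, names, ids = [], [], []
    influence = []
    for p in sorted((BASE / "dialogs").glob("*.tsv")):
        dyad = load_dyad_text(p)
        meta = load_json(p.with_suffix(p.suffix + ".json"))
        q = assign_labels(extract_scps(dyad, dialog_id=p.stem), clusters)
        model, report = fit_oim(q.labels, n_states=6)
        params.append(model)
        names.append(meta["class"])
        ids.append(p.stem)
        influence.append(model.theta[0, 0])
    X, headers = embed_cohort(params)
    frame = pd.DataFrame(X, index=ids, columns=headers)
    frame.insert(0, "class", names)
    frame.to_csv(BASE / "scores.tsv", sep="\t", float_format="%.10g")
    print(f"fitted {len(params)} models; score matrix {X.shape[0]} x {X.shape[1]}")
    print(f"mean moderator self-influence theta_11: {np.mean(influence):.2f}")
    print(f"wrote {BASE / 'scores.tsv'}")


if __name__ == "__main__":
    main()
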