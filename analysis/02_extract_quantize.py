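#!/usr/bin/env python
"""Extract Steady Conversational Periods and fit the duration quantizer.

Writes the per-class speech/silence sample fractions (the cohort-profile
table) and the fitted per-type cluster boundaries in seconds (the
quantizer table), then labels every SCP with one of the 6 states.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scpoim.io import dump_json, load_dyad_text, load_json
from scpoim.quantize import fit_duration_gmm, pool_durations
from scpoim.signal import extract_scps, speech_silence_fractions

BASE = Path(__file__).resolve().parents[1] / "results" / "demo"
SEED = 7


def main() -> None:
    paths = sorted((BASE / "dialogs").glob("*.tsv"))
    if not paths:
        raise SystemExit("run 01_simulate_cohort.py first")
    rows = []
    scps = []
    for p in paths:
        dyad = load_dyad_text(p)
        meta = load_json(p.with_suffix(p.suffix + ".json"))
        scps.append(extract_scps(dyad, dialog_id=p.stem))
        fr = speech_silence_fractions(dyad)
        for chain, (speech, silence) in fr.items():
            rows.append(
                {"dialog": p.stem, "class": meta["class"], "chain": chain,
                 "speech": speech, "silence": silence}
            )
    fractions = pd.DataFrame(rows)
    profile = fractions.groupby(["class", "chain"])[["speech", "silence"]].mean().round(3)
    profile.to_csv(BASE / "speech_silence_fractions.tsv", sep="\t")
    print("mean speech/silence sample fractions:")
    print(profile)

    clusters = fit_duration_gmm(pool_durations(scps), k=3, seed=SEED)
    table = pd.DataFrame(
        {
            t: np.concatenate([c.boundaries, [np.nan]])
            for t, c in clusters.by_type.items()
        },
        index=["short|medium (s)", "medium|long (s)", ""],
    ).iloc[:2]
    table.round(2).to_csv(BASE / "cluster_boundaries.tsv", sep="\t")
    print("\nduration cluster boundaries (seconds):")
    print(table.round(2))
    dump_json({"clusters": clusters.to_dict(), "seed": SEED}, BASE / "clusters.json")
    print(f"\nwrote quantizer and tables under {BASE}")


if __name__ == "__main__":
    main()
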