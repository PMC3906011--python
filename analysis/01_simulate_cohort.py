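#!/usr/bin/env python
"""Simulate the demo cohort: 9 control + 9 case dyadic dialogs.

The case class differs from the control class in a single generative
transition: 0.3 of probability mass in the moderator's intra-chain
medium-silence row moves from the short-speech target to the long-speech
target.  Dialogs are written as two-column 0/1 sample streams with JSON
sidecars carrying the ground truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scpoim import experiments as ex
from scpoim.io import save_dyad_text
from scpoim.synthetic import generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "demo" / "dialogs"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = ex.make_cohort_specs(effect=0.3, n_dialogs=9, dialog_length=150)
    cohort = generate_cohort(specs, SEED, sample_rate=100.0)
    total_minutes = 0.0
    for rec in cohort.dialogs:
        save_dyad_text(
            rec.dyad,
            OUT / f"{rec.participant_id}.tsv",
            sidecar={
                "class": rec.class_name,
                "true_labels": rec.true_labels,
                "seed": SEED,
            },
        )
        total_minutes += rec.dyad.duration / 60.0
    print(f"wrote {len(cohort)} dialogs to {OUT}")
    print(f"mean dialog length: {total_minutes / len(cohort):.1f} min at 100 Hz")


if __name__ == "__main__":
    main()
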