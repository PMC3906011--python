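#!/usr/bin/env python
"""Classify dialogs in the score space: LOO, separation, accuracy curve.

Reports fold-nested leave-one-out precision/recall on the top-2 features
(each fold re-ranks features on its own training dialogs), resubstitution
"separation" performance, the mean-recall-vs-number-of-features curve, and
a 2-D decision-boundary grid on the two top pooled features.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scpoim.classify import accuracy_curve, decision_boundary_grid, separation_evaluate
from scpoim.experiments import nested_loo_evaluate
from scpoim.io import dump_json, load_json

BASE = Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    frame = pd.read_csv(BASE / "scores.tsv", sep="\t", index_col=0)
    y = frame.pop("class").to_numpy()
    X = frame.to_numpy()
    pooled_order = [f - 1 for f in load_json(BASE / "ranking.json")["order_1based"]]
    top2 = pooled_order[:2]

    out = {}
    for clf in ("knn", "svm"):
        loo, _ = nested_loo_evaluate(X, y, k=2, classifier=clf)
        sep = separation_evaluate(X, y, top2, clf)
        out[clf] = {
            "loo": {"precision": loo.precision, "recall": loo.recall,
                    "mean_recall": loo.mean_recall},
            "separation": {"precision": sep.precision, "recall": sep.recall,
                           "mean_recall": sep.mean_recall},
        }
        print(f"{clf}: nested-LOO mean recall {loo.mean_recall:.2f} "
              f"(precision {['%.2f' % loo.precision[c] for c in loo.classes]}, "
              f"recall {['%.2f' % loo.recall[c] for c in loo.classes]}); "
              f"separation mean recall {sep.mean_recall:.2f}")
    curve = accuracy_curve(X, y, pooled_order, k_max=10)
    pd.DataFrame({"k": np.arange(1, 11), **{c: v for c, v in curve.items()}}).to_csv(
        BASE / "mean_recall_vs_k.tsv", sep="\t", index=False, float_format="%.3f"
    )
    print("mean recall vs k (knn):", np.round(curve["knn"], 2).tolist())

    grid = decision_boundary_grid(X[:, top2], y, "svm", resolution=60)
    pd.DataFrame(grid.labels, index=np.round(grid.y, 4), columns=np.round(grid.x, 4)).to_csv(
        BASE / "boundary_grid_svm.tsv", sep="\t"
    )
    dump_json(out, BASE / "classification_report.json")
    print(f"wrote reports under {BASE}")


if __name__ == "__main__":
    main()
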