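"""End-to-end orchestration: simulate/load -> SCPs -> quantize -> fit ->
embed -> rank -> classify, with config validation and provenance.

Two leakage modes govern the leave-one-out report:

* ``fold`` (default, strict): every LOO fold re-fits the duration
  quantizer and the feature ranking on its training dialogs only, so the
  held-out dialog influences nothing it is later judged by;
* ``pooled``: quantizer and ranking are fitted once on all dialogs, the
  protocol a small-sample study would typically report alongside its
  feature table.  Interpretive artifacts (cluster boundaries, the score
  matrix, the pooled feature ranking) are always computed on the full
  cohort; only the LOO report differs between modes.

Every artifact directory carries a provenance file naming the config hash
and seed, and reruns with an identical config write byte-identical numeric
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import accuracy_curve, loo_evaluate, separation_evaluate
from .experiments import make_cohort_specs, nested_loo_evaluate
from .io import dump_json, load_dyad_text, save_dyad_text
from .oim import fit_oim
from .quantize import assign_labels, fit_duration_gmm, pool_durations
from .scorespace import describe_feature, embed_cohort
from .selection import DEFAULT_POLICIES, stability_rank
from .signal import extract_scps
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["SimulateConfig", "RunConfig", "run_all"]


@dataclass
class SimulateConfig:
    n_dialogs: int = 9
    dialog_length: int = 150
    effect: float = 0.3

    def validate(self) -> None:
        if self.n_dialogs < 2:
            raise ValueError("simulate.n_dialogs must be >= 2")
        if self.dialog_length < 2:
            raise ValueError("simulate.dialog_length must be >= 2")
        if not 0 <= self.effect < 1:
            raise ValueError("simulate.effect must lie in [0, 1)")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    sample_rate: float = 100.0
    n_scales: int = 3
    T: int = 10
    final_k: int = 2
    curve_k_max: int = 10
    policies: tuple = DEFAULT_POLICIES
    classifiers: tuple = ("knn", "svm")
    knn_K: int = 3
    svm_C: float = 100.0
    leakage: str = "fold"
    input_dir: str | None = None
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)

    @property
    def n_states(self) -> int:
        return 2 * self.n_scales

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_scales not in (1, 2, 3):
            raise ValueError("n_scales must be 1, 2 or 3")
        if self.T < 1 or self.final_k < 1 or self.curve_k_max < self.final_k:
            raise ValueError("T >= 1 and 1 <= final_k <= curve_k_max required")
        if self.leakage not in ("fold", "pooled"):
            raise ValueError("leakage must be 'fold' or 'pooled'")
        unknown = set(self.policies) - set(DEFAULT_POLICIES)
        if unknown:
            raise ValueError(f"unknown policies: {sorted(unknown)}")
        if set(self.classifiers) - {"knn", "svm"}:
            raise ValueError("classifiers must be drawn from {'knn', 'svm'}")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either simulate or input_dir must be given")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulateConfig(**sim)
        for key in ("policies", "classifiers"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.validate()
        return cfg

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # where artifacts land does not change what is computed
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _report_dict(report) -> dict:
    return {
        "classifier": report.classifier,
        "mode": report.mode,
        "feature_subset_1based": [int(f) + 1 for f in report.feature_subset],
        "precision": {str(c): report.precision[c] for c in report.classes},
        "recall": {str(c): report.recall[c] for c in report.classes},
        "mean_recall": report.mean_recall,
        "predictions": [str(p) for p in report.predictions],
        "true_labels": [str(t) for t in report.true_labels],
    }


def run_all(config: RunConfig) -> Path:
    """Execute every stage and serialize all artifacts under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger("scpoim").addHandler(handler)
    try:
        return _run_all(config, out)
    except Exception as exc:  # annotate stage failures with context
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logging.getLogger("scpoim").removeHandler(handler)
        handler.close()


def _run_all(config: RunConfig, out: Path) -> Path:
    provenance = {
        "config": json.loads(config.canonical()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }

    # -- stage: obtain dialogs ------------------------------------------------
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.tsv"))
        if not paths:
            raise RuntimeError(f"stage load: no .tsv dialogs under {config.input_dir}")
        dyads, names, ids = [], [], []
        for p in paths:
            dyads.append(load_dyad_text(p, sample_rate=config.sample_rate))
            meta_path = p.with_suffix(p.suffix + ".json")
            meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
            names.append(meta.get("class", "unknown"))
            ids.append(p.stem)
        logger.info("loaded %d dialogs from %s", len(dyads), config.input_dir)
    else:
        sim = config.simulate
        specs = make_cohort_specs(
            effect=sim.effect, n_dialogs=sim.n_dialogs, dialog_length=sim.dialog_length
        )
        cohort = generate_cohort(specs, config.seed, sample_rate=config.sample_rate)
        ddir = out / "dialogs"
        ddir.mkdir(exist_ok=True)
        dyads, names, ids = [], [], []
        for rec in cohort.dialogs:
            save_dyad_text(
                rec.dyad,
                ddir / f"{rec.participant_id}.tsv",
                sidecar={
                    "class": rec.class_name,
                    "true_labels": rec.true_labels,
                    "truncated": rec.truncated,
                    "merge_events": rec.merge_events,
                    "config_hash": provenance["config_hash"],
                },
            )
            dyads.append(rec.dyad)
            names.append(rec.class_name)
            ids.append(rec.participant_id)
        logger.info("simulated %d dialogs", len(dyads))
    y = np.array(names)

    # -- stage: SCP extraction -------------------------------------------------
    scps = []
    for dyad, did in zip(dyads, ids):
        try:
            scps.append(extract_scps(dyad, dialog_id=did))
        except Exception as exc:
            raise RuntimeError(f"stage scps failed on dialog {did}: {exc}") from exc

    # -- stage: quantization (pooled, interpretive) ---------------------------
    clusters = fit_duration_gmm(pool_durations(scps), k=config.n_scales, seed=config.seed)
    dump_json(
        {"clusters": clusters.to_dict(), "provenance": provenance}, out / "clusters.json"
    )

    # -- stage: OIM fits and embedding ----------------------------------------
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    params = []
    for scp, did in zip(scps, ids):
        q = assign_labels(scp, clusters)
        try:
            p, _ = fit_oim(q.labels, n_states=config.n_states)
        except Exception as exc:
            raise RuntimeError(f"stage fit failed on dialog {did}: {exc}") from exc
        params.append(p)
        dump_json({"model": p.to_dict(), "dialog": did, "provenance": provenance},
                  mdir / f"{did}.json")
    X, headers = embed_cohort(params)
    frame = pd.DataFrame(X, index=ids, columns=headers)
    frame.insert(0, "class", names)
    frame.to_csv(out / "scores.tsv", sep="\t", float_format="%.10g")

    # -- stage: pooled stability ranking (interpretive table) -----------------
    ranking = stability_rank(X, y, policies=config.policies, T=config.T)
    dump_json(
        {
            "order_1based": [f + 1 for f in ranking.order],
            "frequencies": ranking.frequencies,
            "n_instances": ranking.n_instances,
            "top": [
                {
                    "feature_1based": f + 1,
                    "frequency": float(ranking.frequencies[f]),
                    "descriptor": describe_feature(f + 1, config.n_states),
                }
                for f in ranking.order[: config.T]
            ],
            "provenance": provenance,
        },
        out / "ranking.json",
    )

    # -- stage: classification reports ----------------------------------------
    reports = {}
    top_pooled = ranking.order[: config.final_k]
    for clf in config.classifiers:
        if config.leakage == "fold":
            rep, fold_features = nested_loo_evaluate(
                X, y, k=config.final_k, T=config.T, policies=config.policies,
                classifier=clf, K=config.knn_K, svm_C=config.svm_C,
            )
            rep_d = _report_dict(rep)
            rep_d["fold_features_1based"] = [[f + 1 for f in ff] for ff in fold_features]
        else:
            rep = loo_evaluate(X, y, top_pooled, clf, K=config.knn_K, svm_C=config.svm_C)
            rep_d = _report_dict(rep)
        sep = separation_evaluate(X, y, top_pooled, clf, K=config.knn_K, svm_C=config.svm_C)
        reports[clf] = {"loo": rep_d, "separation": _report_dict(sep)}
    curve = accuracy_curve(
        X, y, ranking, min(config.curve_k_max, X.shape[1]),
        classifiers=config.classifiers, K=config.knn_K, svm_C=config.svm_C,
    )
    dump_json(
        {
            "leakage": config.leakage,
            "reports": reports,
            "mean_recall_vs_k": {clf: vals for clf, vals in curve.items()},
            "provenance": provenance,
        },
        out / "report.json",
    )
    dump_json(provenance, out / "provenance.json")
    logger.info("pipeline complete: %s", out)
    return out
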