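"""Study orchestration: simulate/ingest -> extract -> screen -> resample ->
select -> evaluate, with every artifact written to an output directory.

Two evaluation paths are supported, mirroring the two study designs:

* **balanced path** — stratified 60/40 holdout; forward selection on the
  training split; the selected subset evaluated on the test split with each
  classifier;
* **imbalanced path** — 10-fold stratified CV and/or LOOCV on the full
  table, optionally after SMOTE or hybrid SMOTE-Tomek resampling.

Every artifact is stamped with the configuration hash and seed so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import CLASSIFIER_KINDS, make_classifier
from .datatypes import BENIGN, FEATURE_COLUMNS, LABEL_COLUMN, MALIGNANT
from .features import QUSFeatureExtractor
from .io import load_rf_dataset, write_feature_table, write_json_report
from .metrics import cross_validate, rank_sum_screen
from .resampling import SMOTE, SMOTETomek
from .selection import SequentialForwardSelector
from .simulate import SimConfig, simulate_lesion_dataset
from .spectral import SpectralConfig

__all__ = ["RunConfig", "run_study"]

logger = logging.getLogger("qustc")

_RESAMPLERS = ("none", "smote", "smote_tomek")


@dataclass
class RunConfig:
    """Validated run configuration (loadable from YAML)."""

    output_dir: str = "qustc_run"
    dataset_path: str | None = None  # mutually exclusive with simulation
    simulation: dict = field(
        default_factory=lambda: {"n_benign": 10, "n_malignant": 10,
                                 "scans_per_lesion": 2}
    )
    spectral: dict = field(default_factory=dict)
    hk_lookup: dict = field(default_factory=dict)
    classifiers: tuple[str, ...] = ("knn", "svm_linear", "random_forest")
    schemes: tuple[str, ...] = ("holdout",)
    resampler: str = "none"
    leakage_mode: str = "dataset"
    sfs_classifier: str = "knn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resampler not in _RESAMPLERS:
            raise ValueError(f"unknown resampler {self.resampler!r}; choose from {_RESAMPLERS}")
        for c in tuple(self.classifiers) + (self.sfs_classifier,):
            if c not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier {c!r}")
        for s in self.schemes:
            if s not in ("holdout", "kfold", "loocv"):
                raise ValueError(f"unknown scheme {s!r}")
        if self.dataset_path is not None and not Path(self.dataset_path).exists():
            raise ValueError(f"dataset_path does not exist: {self.dataset_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def make_resampler(self):
        if self.resampler == "none":
            return None
        if self.resampler == "smote":
            return SMOTE(random_state=self.seed)
        return SMOTETomek(random_state=self.seed)


def _load_lesions(config: RunConfig):
    if config.dataset_path is not None:
        return load_rf_dataset(config.dataset_path)
    sim = dict(config.simulation)
    base_kwargs = sim.pop("base_config", {})
    return simulate_lesion_dataset(
        n_benign=sim.pop("n_benign", 10),
        n_malignant=sim.pop("n_malignant", 10),
        scans_per_lesion=sim.pop("scans_per_lesion", 2),
        base_config=SimConfig(**base_kwargs) if base_kwargs else None,
        seed=sim.pop("seed", config.seed),
        **sim,
    )


def run_study(config: RunConfig) -> Path:
    """Run the configured study end to end; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    log_lines = []

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s", name)

        def done():
            dt = time.perf_counter() - t0
            log_lines.append(f"{name}: {dt:.2f}s")

        return done

    completed = []
    try:
        done = stage("ingest")
        lesions = _load_lesions(config)
        done()
        completed.append("ingest")

        done = stage("extract")
        extractor = QUSFeatureExtractor(
            spectral_config=SpectralConfig(**config.spectral),
            hk_lookup_kwargs=dict(config.hk_lookup),
        ).fit()
        table = extractor.transform(lesions)
        write_feature_table(table, out / "features.csv")
        done()
        completed.append("extract")

        done = stage("screen")
        ben = table[table[LABEL_COLUMN] == BENIGN][FEATURE_COLUMNS]
        mal = table[table[LABEL_COLUMN] == MALIGNANT][FEATURE_COLUMNS]
        screen = rank_sum_screen(ben, mal)
        screen.to_csv(out / "screen.csv")
        done()
        completed.append("screen")

        X = table[FEATURE_COLUMNS]
        y = table[LABEL_COLUMN].to_numpy()
        resampler = config.make_resampler()
        reports = {}

        if "holdout" in config.schemes:
            done = stage("select")
            from sklearn.model_selection import train_test_split

            tr, te = train_test_split(
                np.arange(len(y)), train_size=0.6, stratify=y,
                random_state=config.seed,
            )
            selector = SequentialForwardSelector(
                make_classifier(config.sfs_classifier, seed=config.seed),
                random_state=config.seed,
            ).fit(X.iloc[tr], y[tr])
            write_json_report(
                {**stamp, "selected": selector.selected_names_,
                 "criteria": selector.trace_.criteria,
                 "log": selector.trace_.log},
                out / "sfs_trace.json",
            )
            done()
            completed.append("select")

            done = stage("evaluate-holdout")
            Xs = selector.transform(X).to_numpy()
            for kind in config.classifiers:
                model = make_classifier(kind, seed=config.seed).fit(Xs[tr], y[tr])
                from .classifiers import predict_scores
                from .metrics import compute_metrics

                rep = compute_metrics(
                    y[te], predict_scores(model, Xs[te]), model.predict(Xs[te]),
                    seed=config.seed, scheme="holdout(0.60)", n_fits=1,
                )
                reports[f"holdout_{kind}"] = rep
            done()
            completed.append("evaluate-holdout")

        for scheme in config.schemes:
            if scheme == "holdout":
                continue
            done = stage(f"evaluate-{scheme}")
            for kind in config.classifiers:
                rep = cross_validate(
                    X.to_numpy(), y, make_classifier(kind, seed=config.seed),
                    scheme=scheme, resampler=resampler,
                    leakage_mode=config.leakage_mode, seed=config.seed,
                )
                reports[f"{scheme}_{kind}"] = rep
            done()
            completed.append(f"evaluate-{scheme}")

        for name, rep in reports.items():
            write_json_report({**stamp, **rep.to_dict()}, out / f"eval_{name}.json")
            pd.DataFrame({"fpr": rep.roc_fpr, "tpr": rep.roc_tpr}).to_csv(
                out / f"roc_{name}.csv", index=False
            )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        write_json_report({**stamp, "stages": completed}, out / "run_summary.json")
    except Exception:
        write_json_report(
            {**stamp, "stages": completed, "status": "failed"},
            out / "run_summary.json",
        )
        raise
    return out
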