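"""End-to-end pipeline orchestration: config, train/test splitting, artifacts.

A run is described by a :class:`RunConfig` (serializable to YAML); its
artifacts (pair sets, encoding, ranking, IFS curve, model archive, metrics)
are written to an output directory alongside the config and its hash, so a
rerun with the same config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import DEFAULT_SEED, ClassifierSpec
from .diagnosis import GenePairDiagnosis
from .io import CASE, CONTROL, read_expression_matrix, read_gene_list, read_labels
from .metrics import write_metrics
from .ranking import RankedFeatureList
from .reo import write_pair_set

logger = logging.getLogger(__name__)


def split_train_test(
    labels: pd.Series,
    fraction: float = 0.8,
    strata: pd.Series | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[list[str], list[str]]:
    """Deterministic stratified train/test split of sample ids.

    Stratified by class, and additionally by an optional per-sample
    attribute (e.g. biopsy vs surgery specimen type).  The split is exact
    and disjoint: per stratum, ``floor(fraction * n)`` samples (at least 1)
    go to training.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    if strata is not None:
        keys = labels.astype(str) + "\t" + strata.loc[labels.index].astype(str)
    else:
        keys = labels.astype(str)
    train: list[str] = []
    test: list[str] = []
    for key in sorted(keys.unique()):
        ids = np.array(sorted(labels.index[keys == key]))
        if len(ids) < 1:
            continue
        n_train = max(1, int(np.floor(fraction * len(ids) + 1e-9)))
        if n_train >= len(ids):
            n_train = len(ids) - 1 if len(ids) > 1 else 1
        perm = rng.permutation(len(ids))
        train += ids[perm[:n_train]].tolist()
        test += ids[perm[n_train:]].tolist()
    return sorted(train), sorted(test)


@dataclass
class RunConfig:
    matrix: str = ""
    labels: str = ""
    whitelist: str | None = None
    out_dir: str = "reopair_run"
    threshold: float = 0.85
    ranking: str = "mrmr"
    classifier: str = "svm_rbf"
    classifier_params: dict = field(default_factory=dict)
    metric: str = "accuracy"
    cv: int = 0
    max_features: int | None = None
    split_fraction: float | None = None  # None = train on all labeled samples
    seed: int = DEFAULT_SEED
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write artifacts under ``config.out_dir``.

    Stages: (optional stratified split) -> stable-pair mining on training
    samples -> reversal detection -> whitelist filtering -> ternary
    encoding -> feature ranking -> incremental feature selection -> fit ->
    evaluation (training resubstitution, plus held-out metrics when a
    split fraction is configured).  Returns a dict of artifact paths.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for name in ("matrix", "labels"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path!r}")
    if config.whitelist and not Path(config.whitelist).exists():
        raise FileNotFoundError(f"whitelist file not found: {config.whitelist!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "config.hash").write_text(config.digest() + "\n")

    matrix = read_expression_matrix(config.matrix)
    labels = read_labels(config.labels)
    whitelist = read_gene_list(config.whitelist) if config.whitelist else None

    test_ids: list[str] = []
    if config.split_fraction is not None:
        train_ids, test_ids = split_train_test(
            labels, fraction=config.split_fraction, seed=config.seed
        )
        train_labels = labels.loc[train_ids]
    else:
        train_labels = labels

    spec = ClassifierSpec.make(
        config.classifier, seed=config.seed, **config.classifier_params
    )
    model = GenePairDiagnosis(
        matrix,
        train_labels,
        whitelist=whitelist,
        threshold=config.threshold,
        ranking=config.ranking,
        classifier=spec,
    )
    results = model.fit(
        metric=config.metric, cv=config.cv, max_features=config.max_features
    )

    artifacts = {
        "config": str(out / "config.yaml"),
        "stable_case": str(out / "stable_case.tsv"),
        "stable_control": str(out / "stable_control.tsv"),
        "reversal_pairs": str(out / "reversal_pairs.tsv"),
        "encoded": str(out / "encoded.tsv"),
        "ranking": str(out / "ranking.tsv"),
        "ifs_curve": str(out / "ifs_curve.tsv"),
        "signature": str(out / "signature.tsv"),
        "train_metrics": str(out / "train_metrics.tsv"),
        "summary": str(out / "summary.txt"),
        "model": str(out / "model.joblib"),
    }
    write_pair_set(sorted(results.stable_case.pairs, key=lambda p: p.pair_id),
                   artifacts["stable_case"])
    write_pair_set(sorted(results.stable_control.pairs, key=lambda p: p.pair_id),
                   artifacts["stable_control"])
    write_pair_set(results.candidate_pairs, artifacts["reversal_pairs"])
    results.encoded.to_tsv(artifacts["encoded"])
    results.ranked.to_tsv(artifacts["ranking"])
    results.ifs.curve_frame().to_csv(artifacts["ifs_curve"], sep="\t", index=False)
    from .signature import write_signature

    write_signature(results.signature, artifacts["signature"])
    write_metrics(results.training_metrics(), artifacts["train_metrics"])
    Path(artifacts["summary"]).write_text(results.summary() + "\n")
    _save_model(results, artifacts["model"], config)

    if test_ids:
        test_metrics = results.evaluate(
            matrix.loc[:, test_ids], labels.loc[test_ids]
        )
        artifacts["test_metrics"] = str(out / "test_metrics.tsv")
        write_metrics(test_metrics, artifacts["test_metrics"])
    return artifacts


def _save_model(results, path: str, config: RunConfig) -> None:
    """Versioned model archive: spec + feature list + fitted estimator."""
    import joblib

    payload = {
        "format_version": 1,
        "config_digest": config.digest(),
        "classifier_spec": results.predictor.spec,
        "features": results.predictor.features,
        "estimator": results.predictor.estimator,
        "case_prevalence": results.predictor.case_prevalence,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path):
    """Load a model archive back into a :class:`TrainedPredictor`."""
    import joblib

    from .classify import TrainedPredictor

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version in {path}")
    return TrainedPredictor(
        spec=payload["classifier_spec"],
        features=payload["features"],
        estimator=payload["estimator"],
        case_prevalence=payload["case_prevalence"],
    )
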