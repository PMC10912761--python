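"""Two-class evaluation metrics: confusion counts, sensitivity/specificity/
accuracy/F1, and ROC AUC with a 95% confidence interval.

AUC equals the Mann-Whitney concordance probability (ties get half
credit).  The confidence interval uses DeLong's analytic method by
default — deterministic, hence test-friendly — with a seeded bootstrap as
an option.  Undefined metrics (e.g. sensitivity with no positives) raise
rather than silently returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CASE, CONTROL


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has an empty denominator (e.g. no positive samples)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def positives(self) -> int:  # P = TP + FN (case samples)
        return self.tp + self.fn

    @property
    def negatives(self) -> int:  # N = TN + FP (control samples)
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None = None
    auc_ci_low: float | None = None
    auc_ci_high: float | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
        }


def confusion_counts(
    predicted: Sequence[str], truth: Sequence[str]
) -> ConfusionCounts:
    """Exact integer confusion counts; positive class = case."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    for name, arr in (("predicted", predicted), ("truth", truth)):
        bad = set(np.unique(arr)) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown labels in {name}: {sorted(bad)}")
    tp = int(np.sum((predicted == CASE) & (truth == CASE)))
    fp = int(np.sum((predicted == CASE) & (truth == CONTROL)))
    tn = int(np.sum((predicted == CONTROL) & (truth == CONTROL)))
    fn = int(np.sum((predicted == CONTROL) & (truth == CASE)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy and F1 from confusion counts.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); Acc = (TP+TN)/n; F1 = 2TP/(2TP+FP+FN).
    """
    if c.positives == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples (P = 0)")
    if c.negatives == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples (N = 0)")
    sn = c.tp / c.positives
    sp = c.tn / c.negatives
    acc = (c.tp + c.tn) / c.total
    f1_denom = 2 * c.tp + c.fp + c.fn
    if f1_denom == 0:
        raise UndefinedMetricError("F1 undefined: no positive predictions or samples")
    f1 = 2 * c.tp / f1_denom
    return MetricsReport(sensitivity=sn, specificity=sp, accuracy=acc, f1=f1)


def _binary_truth(truth: Sequence[str]) -> np.ndarray:
    truth = np.asarray(truth)
    bad = set(np.unique(truth)) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return (truth == CASE).astype(int)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(scores_case: np.ndarray, scores_control: np.ndarray):
    """AUC and its DeLong variance via midrank structural components."""
    m, n = len(scores_case), len(scores_control)
    all_scores = np.concatenate([scores_case, scores_control])
    r_all = _midranks(all_scores)
    r_case = _midranks(scores_case)
    r_control = _midranks(scores_control)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (r_all[:m] - r_case) / n          # per-case structural components
    v10 = 1.0 - (r_all[m:] - r_control) / m  # per-control structural components
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    return float(auc), float(var)


def roc_auc_ci(
    scores: Sequence[float],
    truth: Sequence[str],
    alpha: float = 0.05,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 20240304,
) -> tuple[float, float, float]:
    """Empirical ROC AUC with a (1 - alpha) confidence interval.

    AUC is the Mann-Whitney probability that a random case sample scores
    above a random control sample, with half credit for ties.  The default
    CI is DeLong's analytic normal interval; ``method="bootstrap"`` uses
    ``n_boot`` seeded stratified resamples (percentile interval).  The CI
    is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_truth(truth)
    if scores.shape != y.shape:
        raise ValueError("scores and truth lengths differ")
    s_case = scores[y == 1]
    s_control = scores[y == 0]
    if len(s_case) == 0 or len(s_control) == 0:
        raise ValueError("both classes must be present to compute AUC")
    auc, var = _delong_auc_variance(s_case, s_control)
    if method == "delong":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bc = rng.choice(s_case, size=len(s_case), replace=True)
            bk = rng.choice(s_control, size=len(s_control), replace=True)
            boots[b], _ = _delong_auc_variance(bc, bk)
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return auc, float(max(lo, 0.0)), float(min(hi, 1.0))


def roc_points(scores: Sequence[float], truth: Sequence[str]) -> pd.DataFrame:
    """ROC curve points (FPR on the x-axis, TPR on the y-axis, thresholds)."""
    from sklearn.metrics import roc_curve

    y = _binary_truth(truth)
    fpr, tpr, thresholds = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def evaluate_predictions(
    predicted: Sequence[str],
    truth: Sequence[str],
    scores: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> MetricsReport:
    """Full metric report; AUC/CI included when scores are supplied."""
    report = classification_metrics(confusion_counts(predicted, truth))
    if scores is not None:
        auc, lo, hi = roc_auc_ci(scores, truth, alpha=alpha)
        report = MetricsReport(
            sensitivity=report.sensitivity,
            specificity=report.specificity,
            accuracy=report.accuracy,
            f1=report.f1,
            auc=auc,
            auc_ci_low=lo,
            auc_ci_high=hi,
        )
    return report


def write_metrics(report: MetricsReport, path: str | Path, fmt: str = "tsv") -> None:
    d = report.to_dict()
    if fmt == "json":
        import json

        Path(path).write_text(json.dumps(d, indent=2) + "\n")
    else:
        frame = pd.DataFrame([d])
        frame.to_csv(path, sep="\t", index=False)
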