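"""Classifiers over ternary pair-features, incremental feature selection,
and prediction for new encoded samples.

The classifier grid mirrors a standard two-class toolchain: SVM with an RBF
kernel (gamma fixed at 2), k-nearest neighbours (k = 1 by default), a
CART-style decision tree, logistic regression, XGBoost (25 rounds,
binary-logistic objective), AdaBoost over decision stumps, and Gaussian
naive Bayes.  ``logistic_model_tree`` is approximated by logistic
regression; the tree and LMT substitutes are standard CART/LR stand-ins
for Weka's J48/LMT and are not claimed to be equivalent to them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reo import EncodedMatrix, GenePair, labels_to_binary
from .ranking import RankedFeatureList

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20240304

CLASSIFIER_KINDS = (
    "svm_rbf",
    "knn",
    "decision_tree",
    "logistic_regression",
    "xgboost",
    "adaboost_stumps",
    "naive_bayes",
    "logistic_model_tree",
)

# short CLI aliases
KIND_ALIASES = {
    "svm": "svm_rbf",
    "dt": "decision_tree",
    "lr": "logistic_regression",
    "xgb": "xgboost",
    "ada": "adaboost_stumps",
    "nb": "naive_bayes",
    "lmt": "logistic_model_tree",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind + hyperparameters + seed; defaults follow the
    published settings where they are stated (SVM-RBF gamma = 2, XGBoost
    25 rounds with a binary-logistic objective, AdaBoost decision stumps)."""

    kind: str = "svm_rbf"
    params: tuple = field(default_factory=tuple)  # sorted (key, value) pairs
    seed: int = DEFAULT_SEED

    @classmethod
    def make(cls, kind: str, seed: int = DEFAULT_SEED, **params) -> "ClassifierSpec":
        kind = KIND_ALIASES.get(kind, kind)
        if kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}"
            )
        return cls(kind=kind, params=tuple(sorted(params.items())), seed=seed)

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def build(self):
        """Instantiate the underlying scikit-learn / xgboost estimator."""
        p = self.param_dict
        if self.kind == "svm_rbf":
            from sklearn.svm import SVC

            return SVC(
                kernel="rbf",
                gamma=p.get("gamma", 2.0),
                C=p.get("C", 1.0),
                random_state=self.seed,
            )
        if self.kind == "knn":
            from sklearn.neighbors import KNeighborsClassifier

            return KNeighborsClassifier(n_neighbors=p.get("k", 1))
        if self.kind == "decision_tree":
            from sklearn.tree import DecisionTreeClassifier

            return DecisionTreeClassifier(random_state=self.seed)
        if self.kind in ("logistic_regression", "logistic_model_tree"):
            from sklearn.linear_model import LogisticRegression

            return LogisticRegression(max_iter=p.get("max_iter", 1000))
        if self.kind == "xgboost":
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=p.get("rounds", 25),
                objective="binary:logistic",
                random_state=self.seed,
                verbosity=0,
                n_jobs=1,
            )
        if self.kind == "adaboost_stumps":
            from sklearn.ensemble import AdaBoostClassifier
            from sklearn.tree import DecisionTreeClassifier

            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=p.get("rounds", 50),
                random_state=self.seed,
            )
        if self.kind == "naive_bayes":
            from sklearn.naive_bayes import GaussianNB

            return GaussianNB()
        raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class TrainedPredictor:
    """A fitted classifier bound to an ordered pair-feature list.

    Prediction requires exactly the stored features, in order; the stored
    training-class prevalence is kept for score calibration/reporting only.
    """

    spec: ClassifierSpec
    features: list[GenePair]
    estimator: object
    case_prevalence: float

    @property
    def feature_ids(self) -> list[str]:
        return [p.pair_id for p in self.features]


def _design(encoded: EncodedMatrix, features: Sequence[GenePair]) -> np.ndarray:
    return encoded.restrict(list(features)).codes.to_numpy(dtype=float).T


def train_classifier(
    encoded: EncodedMatrix,
    labels: pd.Series,
    spec: ClassifierSpec,
    features: Sequence[GenePair] | None = None,
) -> TrainedPredictor:
    """Fit a classifier on (a feature subset of) the encoded matrix.

    Deterministic given ``spec.seed``.  Requires both classes with at least
    two samples each.
    """
    features = list(features) if features is not None else list(encoded.pairs)
    if not features:
        raise ValueError("feature list is empty")
    y = labels_to_binary(labels, encoded.sample_ids)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"need >= 2 samples per class, got case={counts[1]}, control={counts[0]}"
        )
    X = _design(encoded, features)
    estimator = spec.build()
    estimator.fit(X, y)
    return TrainedPredictor(
        spec=spec,
        features=features,
        estimator=estimator,
        case_prevalence=float(counts[1] / counts.sum()),
    )


def predict(
    predictor: TrainedPredictor, encoded_new: EncodedMatrix
) -> tuple[pd.Series, pd.Series]:
    """Predict case/control labels and decision scores for new samples.

    Scores are oriented so that higher means case (usable directly for a
    ROC curve).  Each sample is encoded and classified independently; the
    prediction for one sample never depends on the rest of the batch.
    """
    missing = [
        p.pair_id for p in predictor.features if p.pair_id not in encoded_new.codes.index
    ]
    if missing:
        raise KeyError(f"encoding lacks the predictor's pairs: {missing[:5]}")
    X = _design(encoded_new, predictor.features)
    uninformative = np.all(X == -1, axis=1)
    if uninformative.any():
        ids = np.asarray(encoded_new.sample_ids)[uninformative]
        logger.warning(
            "samples with every signature gene absent (all codes -1): %s",
            ids.tolist()[:5],
        )
    est = predictor.estimator
    if hasattr(est, "decision_function"):
        scores = np.asarray(est.decision_function(X), dtype=float)
    else:
        scores = np.asarray(est.predict_proba(X)[:, 1], dtype=float)
    y_hat = np.asarray(est.predict(X), dtype=int)
    index = pd.Index(encoded_new.sample_ids, name="sample_id")
    labels_out = pd.Series(
        np.where(y_hat == 1, "case", "control"), index=index, name="predicted"
    )
    return labels_out, pd.Series(scores, index=index, name="score")


@dataclass
class IFSResult:
    """Per-k metric curve from incremental feature selection.

    ``k_opt`` is the smallest k attaining the curve maximum; ``predictor``
    is refitted on the top-``k_opt`` features.
    """

    metric: str
    curve: np.ndarray  # metric value for k = 1..K
    k_opt: int
    predictor: TrainedPredictor
    features: list[GenePair]  # the ranked features the curve walked

    @property
    def best_metric(self) -> float:
        return float(self.curve[self.k_opt - 1])

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, len(self.curve) + 1), self.metric: self.curve}
        )


def _evaluate_metric(y_true: np.ndarray, y_pred: np.ndarray, metric: str) -> float:
    from sklearn.metrics import accuracy_score, f1_score

    if metric in ("accuracy", "acc"):
        return float(accuracy_score(y_true, y_pred))
    if metric == "f1":
        return float(f1_score(y_true, y_pred, zero_division=0))
    raise ValueError(f"unknown metric {metric!r}; use 'accuracy' or 'f1'")


def incremental_feature_selection(
    ranked: RankedFeatureList,
    encoded: EncodedMatrix,
    labels: pd.Series,
    spec: ClassifierSpec,
    metric: str = "accuracy",
    cv: int = 0,
    max_k: int | None = None,
) -> IFSResult:
    """Walk the ranked list, fitting on the top-k features for k = 1..K.

    By default each k is scored by resubstitution on the training samples
    (the protocol the perfect training-set tables imply); ``cv > 1``
    switches to stratified k-fold cross-validation as the safer protocol.
    ``k_opt`` is the smallest prefix length attaining the maximum of the
    curve; the returned predictor is refit on all samples at k_opt.
    """
    if len(ranked) == 0:
        raise ValueError("ranked feature list is empty")
    K = len(ranked) if max_k is None else min(max_k, len(ranked))
    y = labels_to_binary(labels, encoded.sample_ids)
    curve = np.empty(K)
    for k in range(1, K + 1):
        feats = ranked.top(k)
        X = _design(encoded, feats)
        if cv and cv > 1:
            from sklearn.model_selection import StratifiedKFold, cross_val_predict

            skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=spec.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y_pred = cross_val_predict(spec.build(), X, y, cv=skf)
        else:
            est = spec.build()
            est.fit(X, y)
            y_pred = est.predict(X)
        curve[k - 1] = _evaluate_metric(y, np.asarray(y_pred, dtype=int), metric)
    k_opt = int(np.argmax(curve)) + 1  # argmax returns the first (smallest) maximizer
    predictor = train_classifier(encoded, labels, spec, features=ranked.top(k_opt))
    return IFSResult(
        metric=metric,
        curve=curve,
        k_opt=k_opt,
        predictor=predictor,
        features=list(ranked.features[:K]),
    )
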