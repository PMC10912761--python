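"""Model/Results facade over the full gene-pair signature workflow.

``GenePairDiagnosis`` is constructed from an expression matrix and class
labels (statsmodels-style); ``.fit()`` runs stable-pair mining, reversal
detection, optional whitelist filtering, ternary encoding, feature ranking
(mRMR or MRMD) and incremental feature selection with the chosen
classifier, and returns a ``GenePairDiagnosisResults`` carrying the
discovered signature, the IFS curve, the fitted predictor and the
training-set metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .classify import ClassifierSpec, IFSResult, TrainedPredictor
from .classify import incremental_feature_selection, predict as _predict
from .io import CASE, CONTROL, validate_labels, validate_matrix
from .ranking import RankedFeatureList, mrmd_rank, mrmr_rank
from .reo import (
    EncodedMatrix,
    ReversalPairSet,
    StablePairSet,
    encode_profiles,
    filter_pairs_by_gene_set,
    find_reversal_pairs,
    mine_stable_pairs,
)
from .signature import GenePairSignature

logger = logging.getLogger(__name__)

RANKERS = {"mrmr": mrmr_rank, "mrmd": mrmd_rank}


class GenePairDiagnosis:
    """Two-class rank-based (REO) gene-pair diagnosis model.

    Parameters
    ----------
    matrix
        Genes x samples expression frame; any within-sample monotone scale.
    labels
        sample_id -> {"case", "control"} Series covering the samples to use.
    whitelist
        Optional gene set (e.g. secreted genes); reversal pairs are kept
        only when BOTH genes belong to it.
    threshold
        Within-class stability threshold (inclusive), default 0.85.
    ranking
        "mrmr" or "mrmd".
    classifier
        A :class:`ClassifierSpec`; defaults to SVM-RBF with gamma = 2.
    gene_subset
        Optional restriction of mining to a gene subset for tractability
        (by default the whitelist is applied only after reversal
        detection).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        labels: pd.Series,
        whitelist: Iterable[str] | None = None,
        threshold: float = 0.85,
        ranking: str = "mrmr",
        classifier: ClassifierSpec | None = None,
        gene_subset: Iterable[str] | None = None,
    ):
        validate_matrix(matrix)
        labels = labels.loc[labels.index.intersection(matrix.columns)]
        self.labels = validate_labels(labels, matrix)
        # keep only labeled samples: unlabeled (e.g. held-out) columns must
        # never influence mining, ranking or fitting
        self.matrix = matrix.loc[:, [c for c in matrix.columns if c in labels.index]]
        if ranking not in RANKERS:
            raise ValueError(f"ranking must be one of {sorted(RANKERS)}, got {ranking!r}")
        self.ranking = ranking
        self.threshold = threshold
        self.whitelist = set(whitelist) if whitelist is not None else None
        self.classifier = classifier or ClassifierSpec.make("svm_rbf")
        self.gene_subset = set(gene_subset) if gene_subset is not None else None
        for cls in (CASE, CONTROL):
            if (self.labels == cls).sum() < 2:
                raise ValueError(f"need >= 2 labeled {cls} samples")

    @classmethod
    def from_files(
        cls,
        matrix_path,
        labels_path,
        whitelist_path=None,
        **kwargs,
    ) -> "GenePairDiagnosis":
        from .io import read_expression_matrix, read_gene_list, read_labels

        matrix = read_expression_matrix(matrix_path)
        labels = read_labels(labels_path)
        whitelist = read_gene_list(whitelist_path) if whitelist_path else None
        return cls(matrix, labels, whitelist=whitelist, **kwargs)

    def fit(
        self,
        metric: str = "accuracy",
        cv: int = 0,
        max_features: int | None = None,
    ) -> "GenePairDiagnosisResults":
        """Run the discovery + selection workflow on the labeled samples."""
        case_ids = self.labels.index[self.labels == CASE].tolist()
        ctrl_ids = self.labels.index[self.labels == CONTROL].tolist()
        mining_matrix = self.matrix
        if self.gene_subset is not None:
            mining_matrix = self.matrix.loc[self.matrix.index.isin(self.gene_subset)]

        stable_case = mine_stable_pairs(
            mining_matrix, case_ids, threshold=self.threshold, label=CASE
        )
        stable_control = mine_stable_pairs(
            mining_matrix, ctrl_ids, threshold=self.threshold, label=CONTROL
        )
        logger.info(
            "stable pairs: %d (case), %d (control)", len(stable_case), len(stable_control)
        )
        reversal = find_reversal_pairs(stable_case, stable_control)
        logger.info("reversal pairs: %d", len(reversal))
        candidates = reversal
        if self.whitelist is not None:
            candidates = filter_pairs_by_gene_set(reversal, self.whitelist)
            logger.info("whitelist-filtered pairs: %d", len(candidates))
        if len(candidates) == 0:
            raise ValueError(
                "no candidate reversal pairs survive mining/filtering; "
                "lower the threshold or check the whitelist"
            )

        encoded = encode_profiles(self.matrix, list(candidates.pairs))
        ranked = RANKERS[self.ranking](encoded, self.labels)
        ifs = incremental_feature_selection(
            ranked,
            encoded,
            self.labels,
            self.classifier,
            metric=metric,
            cv=cv,
            max_k=max_features,
        )
        return GenePairDiagnosisResults(
            model=self,
            stable_case=stable_case,
            stable_control=stable_control,
            reversal_pairs=reversal,
            candidate_pairs=candidates,
            encoded=encoded,
            ranked=ranked,
            ifs=ifs,
        )


@dataclass
class GenePairDiagnosisResults:
    """Fit results: discovered pair sets, ranking, IFS curve and predictor."""

    model: GenePairDiagnosis
    stable_case: StablePairSet
    stable_control: StablePairSet
    reversal_pairs: ReversalPairSet
    candidate_pairs: ReversalPairSet
    encoded: EncodedMatrix
    ranked: RankedFeatureList
    ifs: IFSResult

    @property
    def predictor(self) -> TrainedPredictor:
        return self.ifs.predictor

    @property
    def k_opt(self) -> int:
        return self.ifs.k_opt

    @property
    def signature(self) -> GenePairSignature:
        """The optimal pair prefix as a named signature."""
        return GenePairSignature(
            name=f"{self.ranked.method}_{self.model.classifier.kind}_{self.k_opt}",
            pairs=tuple(self.ranked.top(self.k_opt)),
            provenance="discovered by incremental feature selection",
        )

    def training_metrics(self) -> metrics_mod.MetricsReport:
        """Resubstitution metrics of the optimal predictor on the training set."""
        sub = self.encoded.restrict(self.predictor.features)
        labels_hat, scores = _predict(self.predictor, sub)
        truth = self.model.labels.loc[labels_hat.index]
        return metrics_mod.evaluate_predictions(
            labels_hat.to_numpy(), truth.to_numpy(), scores.to_numpy()
        )

    def predict(self, matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        """Labels and case-oriented scores for new samples (per-sample REO only)."""
        encoded = encode_profiles(matrix, self.predictor.features)
        return _predict(self.predictor, encoded)

    def evaluate(
        self, matrix: pd.DataFrame, truth: pd.Series
    ) -> metrics_mod.MetricsReport:
        labels_hat, scores = self.predict(matrix)
        aligned = truth.loc[labels_hat.index]
        return metrics_mod.evaluate_predictions(
            labels_hat.to_numpy(), aligned.to_numpy(), scores.to_numpy()
        )

    def plot_ifs(self, ax=None):
        """IFS curve: metric vs number of top-ranked pairs."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        ks = np.arange(1, len(self.ifs.curve) + 1)
        ax.plot(ks, self.ifs.curve, marker="o", ms=3)
        ax.axvline(self.k_opt, ls="--", color="grey", lw=1)
        ax.set_xlabel("number of gene pairs (ranked)")
        ax.set_ylabel(self.ifs.metric)
        ax.set_title(f"IFS curve ({self.ranked.method} + {self.model.classifier.kind})")
        return ax

    def summary(self) -> str:
        """Human-readable fit summary table."""
        n_case = int((self.model.labels == CASE).sum())
        n_ctrl = int((self.model.labels == CONTROL).sum())
        rep = self.training_metrics()
        lines = [
            "Gene-pair diagnosis (relative expression orderings)",
            "=" * 55,
            f"samples:            {n_case} case / {n_ctrl} control",
            f"stability threshold: {self.model.threshold:.2f}",
            f"stable pairs:        {len(self.stable_case)} (case), "
            f"{len(self.stable_control)} (control)",
            f"reversal pairs:      {len(self.reversal_pairs)}",
            f"candidate pairs:     {len(self.candidate_pairs)}"
            + (" (whitelist-filtered)" if self.model.whitelist is not None else ""),
            f"ranking:             {self.ranked.method}",
            f"classifier:          {self.model.classifier.kind}",
            f"optimal pairs (k):   {self.k_opt}",
            "-" * 55,
            f"training accuracy:   {rep.accuracy:.4f}",
            f"training F1:         {rep.f1:.4f}",
            f"training Sn / Sp:    {rep.sensitivity:.4f} / {rep.specificity:.4f}",
            f"training AUC:        {rep.auc:.4f} "
            f"(95% CI {rep.auc_ci_low:.4f}-{rep.auc_ci_high:.4f})",
            "-" * 55,
            "signature (gene_i above gene_j in case class):",
        ]
        for r, p in enumerate(self.ranked.top(self.k_opt), start=1):
            lines.append(f"  {r:2d}. {p.gene_i} > {p.gene_j}")
        return "\n".join(lines)
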