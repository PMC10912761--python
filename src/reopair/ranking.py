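"""Feature ranking for ternary pair-features: mRMR and MRMD.

mRMR (minimum redundancy, maximum relevance) greedily ranks features by
mutual information with the class label minus the mean mutual information
with already-selected features.  MRMD ranks features by the sum of the
absolute Pearson correlation with the class label (relevance) and the mean
cosine distance to all other features (non-redundancy).  Both operate on
the {-1, 0, 1} codes treated as categorical levels and are deterministic:
ties break lexicographically by pair id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reo import EncodedMatrix, GenePair, labels_to_binary

logger = logging.getLogger(__name__)


@dataclass
class RankedFeatureList:
    """Ordered pair-features with per-feature scores and the ranking method."""

    method: str  # "mRMR" or "MRMD"
    features: list[GenePair]
    scores: list[float]

    def __len__(self) -> int:
        return len(self.features)

    def top(self, k: int) -> list[GenePair]:
        return self.features[:k]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "gene_i": [p.gene_i for p in self.features],
                "gene_j": [p.gene_j for p in self.features],
                "score": self.scores,
                "method": self.method,
            }
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedFeatureList":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
        return cls(
            method=str(frame["method"].iloc[0]),
            features=[GenePair(gi, gj) for gi, gj in zip(frame["gene_i"], frame["gene_j"])],
            scores=[float(s) for s in frame["score"]],
        )


def mutual_information(f: np.ndarray, t: np.ndarray) -> float:
    """Plug-in discrete mutual information in nats.

    ``MI = sum_xy p(x, y) * ln( p(x, y) / (p(x) p(y)) )`` with the usual
    convention ``0 ln 0 = 0``.  Inputs are treated as categorical; features
    take values in {-1, 0, 1} and the class vector is binary.
    """
    f = np.asarray(f)
    t = np.asarray(t)
    if f.shape != t.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {t.shape}")
    if f.size == 0:
        raise ValueError("empty vectors")
    n = f.size
    _, fi = np.unique(f, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    joint = np.zeros((fi.max() + 1, ti.max() + 1))
    np.add.at(joint, (fi, ti), 1.0)
    joint /= n
    pf = joint.sum(axis=1, keepdims=True)
    pt = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (pf @ pt)[nz])))
    return max(mi, 0.0)  # clip away negative rounding error


def _code_rows(encoded: EncodedMatrix) -> tuple[list[GenePair], np.ndarray]:
    return list(encoded.pairs), encoded.codes.to_numpy(dtype=np.int8)


def mrmr_rank(
    encoded: EncodedMatrix, labels: pd.Series, k: int | None = None
) -> RankedFeatureList:
    """Greedy incremental mRMR ranking (difference form).

    The first feature maximizes MI(f, T); each later step selects the
    remaining feature maximizing ``MI(f, T) - mean_{s in S} MI(f, f_s)``
    over the already-selected set S.  The greedy chain is the canonical
    optimizer of the set-level mRMR criterion, which is infeasible to
    maximize exhaustively beyond tiny feature counts.
    """
    pairs, X = _code_rows(encoded)
    K = len(pairs)
    if k is None:
        k = K
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > K:
        raise ValueError(f"k={k} exceeds the {K} available features")
    t = labels_to_binary(labels, encoded.sample_ids)
    if len(np.unique(t)) < 2:
        raise ValueError("both classes must be present for ranking")

    relevance = np.array([mutual_information(X[i], t) for i in range(K)])
    pair_ids = [p.pair_id for p in pairs]
    # pairwise feature-feature MI, filled lazily as features get selected
    ff = np.full((K, K), np.nan)

    selected: list[int] = []
    scores: list[float] = []
    remaining = set(range(K))
    for _ in range(k):
        best_idx, best_score = None, None
        for i in sorted(remaining, key=lambda i: pair_ids[i]):
            if selected:
                for s in selected:
                    if np.isnan(ff[i, s]):
                        ff[i, s] = ff[s, i] = mutual_information(X[i], X[s])
                redundancy = float(np.mean([ff[i, s] for s in selected]))
            else:
                redundancy = 0.0
            score = relevance[i] - redundancy
            if best_score is None or score > best_score + 1e-12:
                best_idx, best_score = i, score
        selected.append(best_idx)
        scores.append(float(best_score))
        remaining.discard(best_idx)
    return RankedFeatureList(
        method="mRMR", features=[pairs[i] for i in selected], scores=scores
    )


def mrmr_set_score(encoded: EncodedMatrix, labels: pd.Series, subset: Sequence[GenePair]) -> float:
    """Set-level mRMR criterion: mean relevance minus mean pairwise redundancy.

    ``(1/|S|) sum_i MI(f_i, T) - (1/|S|^2) sum_{i != j} MI(f_i, f_j)`` — used
    to cross-check the greedy ranking against exhaustive subset search on
    small instances.  Self-terms are excluded from the redundancy sum: a
    feature's MI with itself is its entropy, a property of the feature
    alone, and including it would reward degenerate low-entropy features
    over informative ones.
    """
    sub = encoded.restrict(list(subset))
    _, X = _code_rows(sub)
    t = labels_to_binary(labels, sub.sample_ids)
    m = len(subset)
    rel = np.mean([mutual_information(X[i], t) for i in range(m)])
    red = sum(
        mutual_information(X[i], X[j])
        for i in range(m)
        for j in range(m)
        if i != j
    ) / (m * m)
    return float(rel - red)


def pearson_relevance(f: np.ndarray, t: np.ndarray) -> float:
    """Absolute Pearson correlation |r| between a code vector and 0/1 labels.

    Both reversal directions carry the same information, hence the absolute
    value.  A zero-variance input is degenerate and scores 0 (warned).
    """
    f = np.asarray(f, dtype=float)
    t = np.asarray(t, dtype=float)
    if f.shape != t.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {t.shape}")
    if f.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(f) == 0 or np.std(t) == 0:
        warnings.warn("zero-variance vector in pearson_relevance; returning 0")
        return 0.0
    return float(abs(np.corrcoef(f, t)[0, 1]))


def cosine_distance(f1: np.ndarray, f2: np.ndarray) -> float:
    """Cosine distance ``1 - f1.f2 / (||f1|| ||f2||)``, in [0, 2]."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError(f"length mismatch: {f1.shape} vs {f2.shape}")
    n1, n2 = np.linalg.norm(f1), np.linalg.norm(f2)
    if n1 == 0 or n2 == 0:
        which = "first" if n1 == 0 else "second"
        raise ValueError(f"cosine distance undefined: {which} feature is a zero vector")
    return float(1.0 - np.dot(f1, f2) / (n1 * n2))


def mrmd_rank(
    encoded: EncodedMatrix,
    labels: pd.Series,
    k: int | None = None,
    relevance_weight: float = 1.0,
    distance_weight: float = 1.0,
) -> RankedFeatureList:
    """MRMD ranking: |Pearson(f, T)| plus mean cosine distance to other features.

    ``score_i = w_r * |r(f_i, T)| + w_d * mean_{j != i} d_cos(f_i, f_j)``;
    features are ranked by descending score with lexicographic pair-id
    tie-breaks.  The two terms carry equal unit weights by default.  A
    single feature has distance term 0.  Zero-norm code vectors (all codes
    0) contribute distance 0 with a warning rather than aborting the
    ranking.
    """
    pairs, X = _code_rows(encoded)
    K = len(pairs)
    if k is None:
        k = K
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > K:
        raise ValueError(f"k={k} exceeds the {K} available features")
    t = labels_to_binary(labels, encoded.sample_ids)

    Xf = X.astype(float)
    norms = np.linalg.norm(Xf, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero code vectors in mrmd_rank; "
            "their cosine-distance contribution is 0"
        )
    rel = np.array([pearson_relevance(Xf[i], t) for i in range(K)])
    if K > 1:
        safe = np.where(zero, 1.0, norms)
        cos = (Xf @ Xf.T) / np.outer(safe, safe)
        dist = 1.0 - cos
        dist[zero, :] = 0.0
        dist[:, zero] = 0.0
        np.fill_diagonal(dist, 0.0)
        mean_dist = dist.sum(axis=1) / (K - 1)
    else:
        mean_dist = np.zeros(1)
    score = relevance_weight * rel + distance_weight * mean_dist
    order = sorted(range(K), key=lambda i: (-score[i], pairs[i].pair_id))[:k]
    return RankedFeatureList(
        method="MRMD",
        features=[pairs[i] for i in order],
        scores=[float(score[i]) for i in order],
    )
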