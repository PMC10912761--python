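"""Relative expression orderings (REO): stable-pair mining, reversal
detection, whitelist filtering and ternary encoding.

A gene pair (i, j) is *stable* in a cohort when the strict ordering
``x_i > x_j`` holds in at least a threshold fraction (default 85%) of that
cohort's samples.  A pair stable as ``Gi > Gj`` in the case class and as
``Gi < Gj`` in the control class is a *reversal* pair — the unit feature of
a qualitative, normalization-free signature.  Because only within-sample
orderings are used, every quantity here is invariant under any strictly
increasing per-sample transform of the expression values.

Ties (exact equality) count toward neither ordering during mining and fall
into the ``-1`` catch-all at encoding time, alongside genes absent from the
platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CASE, CONTROL


class PairState(Enum):
    GREATER = "GREATER"
    LESS = "LESS"
    TIE = "TIE"


class GenePair(NamedTuple):
    """Directed gene pair; canonical orientation has gene_i higher in the case class."""

    gene_i: str
    gene_j: str

    @property
    def pair_id(self) -> str:
        return f"{self.gene_i}|{self.gene_j}"

    def swapped(self) -> "GenePair":
        return GenePair(self.gene_j, self.gene_i)

    @classmethod
    def from_id(cls, pair_id: str) -> "GenePair":
        gi, gj = pair_id.split("|")
        return cls(gi, gj)


def pair_state(x_i: float, x_j: float) -> PairState:
    """Strict within-sample ordering of two expression values."""
    if not (math.isfinite(x_i) and math.isfinite(x_j)):
        raise ValueError(f"non-finite expression values: ({x_i}, {x_j})")
    if x_i > x_j:
        return PairState.GREATER
    if x_i < x_j:
        return PairState.LESS
    return PairState.TIE


@dataclass(frozen=True)
class StablePairSet:
    """Directed pairs with ``gene_i > gene_j`` in >= ``threshold`` of the cohort."""

    label: str
    threshold: float
    pairs: frozenset[GenePair]
    n_samples: int = 0

    def __contains__(self, pair: GenePair) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ReversalPairSet:
    """Pairs GREATER-stable in case and LESS-stable in control, case orientation."""

    pairs: tuple[GenePair, ...]
    threshold_case: float = 0.85
    threshold_control: float = 0.85

    def __contains__(self, pair: GenePair) -> bool:
        return pair in set(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def mine_stable_pairs(
    matrix: pd.DataFrame,
    samples: Sequence[str],
    threshold: float = 0.85,
    label: str = "",
) -> StablePairSet:
    """Mine all directed pairs stable at ``threshold`` within ``samples``.

    A pair (i, j) qualifies iff the fraction of the subset's samples with
    strictly ``x_i > x_j`` is >= threshold ("at least", inclusive).  Since
    threshold > 0.5, at most one orientation of an unordered pair qualifies.
    Complexity O(G^2 * n); mining is meant to run on the training samples
    only.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("sample subset is empty")
    unknown = [s for s in samples if s not in matrix.columns]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown[:5]}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to mine stable pairs")
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")

    X = matrix.loc[:, samples].to_numpy(dtype=float)
    genes = matrix.index.to_numpy()
    n = X.shape[1]
    min_count = int(np.ceil(threshold * n - 1e-9))
    pairs: set[GenePair] = set()
    # row-at-a-time broadcast keeps memory at O(G*n) per step
    for a in range(X.shape[0]):
        greater = (X[a][None, :] > X).sum(axis=1)
        hits = np.nonzero(greater >= min_count)[0]
        for b in hits:
            if b != a:
                pairs.add(GenePair(str(genes[a]), str(genes[b])))
    return StablePairSet(
        label=label, threshold=threshold, pairs=frozenset(pairs), n_samples=n
    )


def find_reversal_pairs(
    stable_case: StablePairSet, stable_control: StablePairSet
) -> ReversalPairSet:
    """Intersect case-stable (i, j) with control-stable (j, i).

    The result keeps the case orientation: gene_i is the gene higher in the
    case class.  Concordant pairs (stable in the same direction in both
    classes) are excluded by construction.
    """
    reversed_control = {p.swapped() for p in stable_control.pairs}
    hits = stable_case.pairs & reversed_control
    ordered = tuple(sorted(hits, key=lambda p: p.pair_id))
    return ReversalPairSet(
        pairs=ordered,
        threshold_case=stable_case.threshold,
        threshold_control=stable_control.threshold,
    )


def filter_pairs_by_gene_set(
    pairs: ReversalPairSet, whitelist: Iterable[str]
) -> ReversalPairSet:
    """Keep only pairs whose genes are BOTH in the whitelist (e.g. secreted genes)."""
    allowed = set(whitelist)
    kept = tuple(p for p in pairs.pairs if p.gene_i in allowed and p.gene_j in allowed)
    return ReversalPairSet(
        pairs=kept,
        threshold_case=pairs.threshold_case,
        threshold_control=pairs.threshold_control,
    )


@dataclass
class EncodedMatrix:
    """Pair x sample ternary design matrix.

    Codes: ``0`` when gene_i > gene_j in that sample, ``1`` when
    gene_i < gene_j, ``-1`` for other cases (a gene absent from the
    platform, or an exact tie).  Row index of ``codes`` is the pair id
    ``"genei|genej"``.
    """

    pairs: list[GenePair] = field(default_factory=list)
    codes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def restrict(self, pairs: Sequence[GenePair]) -> "EncodedMatrix":
        ids = [p.pair_id for p in pairs]
        missing = [i for i in ids if i not in self.codes.index]
        if missing:
            raise KeyError(f"pairs not present in encoding: {missing[:5]}")
        return EncodedMatrix(pairs=list(pairs), codes=self.codes.loc[ids])

    def to_tsv(self, path: str | Path) -> None:
        out = self.codes.copy()
        out.index.name = "pair_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EncodedMatrix":
        codes = pd.read_csv(path, sep="\t", index_col=0)
        codes = codes.astype(np.int8)
        pairs = [GenePair.from_id(i) for i in codes.index]
        return cls(pairs=pairs, codes=codes)


def encode_profiles(matrix: pd.DataFrame, pairs: Sequence[GenePair]) -> EncodedMatrix:
    """Encode every sample into ternary pair-space against ``pairs``.

    Genes absent from the matrix give code -1 for that pair in all samples;
    the encoding of one sample never looks at any other sample.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pair list is empty")
    n = matrix.shape[1]
    rows = np.full((len(pairs), n), -1, dtype=np.int8)
    index = set(matrix.index)
    for r, pair in enumerate(pairs):
        if pair.gene_i not in index or pair.gene_j not in index:
            continue  # stays -1: gene not measured on this platform
        xi = matrix.loc[pair.gene_i].to_numpy(dtype=float)
        xj = matrix.loc[pair.gene_j].to_numpy(dtype=float)
        rows[r, xi > xj] = 0
        rows[r, xi < xj] = 1
    codes = pd.DataFrame(
        rows, index=[p.pair_id for p in pairs], columns=matrix.columns
    )
    codes.index.name = "pair_id"
    return EncodedMatrix(pairs=pairs, codes=codes)


def write_pair_set(pairs: Iterable[GenePair], path: str | Path, direction: str = "GREATER") -> None:
    """Serialize a pair set as 3-column TSV: gene_i, gene_j, direction."""
    frame = pd.DataFrame(
        [(p.gene_i, p.gene_j, direction) for p in pairs],
        columns=["gene_i", "gene_j", "direction"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_pair_set(path: str | Path) -> list[GenePair]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [GenePair(gi, gj) for gi, gj in zip(frame["gene_i"], frame["gene_j"])]


def labels_to_binary(labels: pd.Series, sample_ids: Sequence[str]) -> np.ndarray:
    """Map case/control labels to 1/0 aligned with ``sample_ids``."""
    missing = [s for s in sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    aligned = labels.loc[list(sample_ids)]
    bad = set(aligned.unique()) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return (aligned == CASE).to_numpy(dtype=int)
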