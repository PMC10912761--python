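"""Synthetic two-class expression cohorts with planted reversal gene pairs.

The generator emulates the structure the pair-mining pipeline assumes: a
case cohort and a control cohort in which a chosen set of gene pairs keeps
``gene_i > gene_j`` in a controlled fraction of case samples and
``gene_i < gene_j`` in a controlled fraction of control samples, on a
background of genes with no systematic ordering.

Background genes are i.i.d. log-normal per sample (meanlog 5, sdlog 1 by
default — the marginal scale is irrelevant to every downstream quantity by
REO invariance).  For each planted pair, each sample draws a Bernoulli
orientation (probability = the class's stability parameter) and the two
gene values are placed a fixed log-scale separation apart around a
pair-specific baseline, so the realized concordance fraction is under
exact per-sample control: at stability 1.0 the planted orderings hold in
every sample.  Pair baselines are spaced widely apart on the log scale so
orderings *between* different planted pairs stay concordant across
classes (they never masquerade as reversal pairs), and the separation is
kept small against the background spread so background genes rarely sit
stably inside a planted gene's class-to-class swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CASE, CONTROL
from .reo import GenePair


@dataclass(frozen=True)
class SimulationParams:
    n_background_genes: int = 200
    n_planted_pairs: int = 11
    n_case: int = 100
    n_control: int = 50
    stability_case: float = 0.95
    stability_control: float = 0.95
    noise_sd: float = 0.25
    meanlog: float = 5.0
    sdlog: float = 1.0
    delta: float = 0.6       # log-scale half-separation within a planted pair
    pair_spacing: float = 3.0  # log-scale spacing between pair baselines
    seed: int = 20240304

    def __post_init__(self):
        for name in ("n_background_genes", "n_planted_pairs", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("stability_case", "stability_control"):
            v = getattr(self, name)
            if not (0.5 < v <= 1.0):
                raise ValueError(f"{name} must be in (0.5, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.delta <= 0 or self.pair_spacing <= 0:
            raise ValueError("delta and pair_spacing must be > 0")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort pair."""

    planted_pairs: list[GenePair]
    case_fractions: dict[str, float] = field(default_factory=dict)
    control_fractions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_i": [p.gene_i for p in self.planted_pairs],
                "gene_j": [p.gene_j for p in self.planted_pairs],
                "case_fraction_gi_greater": [
                    self.case_fractions[p.pair_id] for p in self.planted_pairs
                ],
                "control_fraction_gi_less": [
                    self.control_fractions[p.pair_id] for p in self.planted_pairs
                ],
            }
        )


def generate_cohorts(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Generate (expression matrix, labels, truth) from ``params``.

    Fully reproducible from ``params.seed``.  Planted genes are named
    ``PG01A``/``PG01B`` (pair 1's gene_i / gene_j) and background genes
    ``BG0001``...; the planted namespace is disjoint from the background
    one.  Realized per-pair ordering fractions are recomputed from the
    emitted matrix and stored in the truth object.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_case + params.n_control
    sample_ids = [f"case_{i+1}" for i in range(params.n_case)] + [
        f"ctrl_{i+1}" for i in range(params.n_control)
    ]
    labels = pd.Series(
        [CASE] * params.n_case + [CONTROL] * params.n_control,
        index=pd.Index(sample_ids, name="sample_id"),
        name="class",
    )
    is_case = np.arange(n) < params.n_case

    bg_names = [f"BG{i+1:04d}" for i in range(params.n_background_genes)]
    background = np.exp(
        rng.normal(params.meanlog, params.sdlog, size=(params.n_background_genes, n))
    )

    P = params.n_planted_pairs
    planted_pairs: list[GenePair] = []
    planted_rows = np.empty((2 * P, n))
    planted_names: list[str] = []
    # Baselines spread symmetrically around meanlog so cross-pair orderings
    # are dominated by the baseline gap, not the class-linked swing.
    offsets = (np.arange(P) - (P - 1) / 2.0) * params.pair_spacing
    for p in range(P):
        mu = params.meanlog + offsets[p]
        gi, gj = f"PG{p+1:02d}A", f"PG{p+1:02d}B"
        planted_pairs.append(GenePair(gi, gj))
        planted_names += [gi, gj]
        # two noisy draws, one high and one low around the baseline
        hi = np.exp(mu + params.delta + rng.normal(0, params.noise_sd, n))
        lo = np.exp(mu - params.delta + rng.normal(0, params.noise_sd, n))
        top = np.maximum(hi, lo)
        bot = np.minimum(hi, lo)
        # orientation per sample: case wants gene_i on top, control gene_j
        want_gi_top = np.where(
            is_case,
            rng.random(n) < params.stability_case,
            ~(rng.random(n) < params.stability_control),
        )
        planted_rows[2 * p] = np.where(want_gi_top, top, bot)
        planted_rows[2 * p + 1] = np.where(want_gi_top, bot, top)

    matrix = pd.DataFrame(
        np.vstack([planted_rows, background]),
        index=pd.Index(planted_names + bg_names, name="gene_id"),
        columns=sample_ids,
    )

    truth = SimulationTruth(planted_pairs=planted_pairs)
    for pair in planted_pairs:
        xi = matrix.loc[pair.gene_i].to_numpy()
        xj = matrix.loc[pair.gene_j].to_numpy()
        truth.case_fractions[pair.pair_id] = float(np.mean(xi[is_case] > xj[is_case]))
        truth.control_fractions[pair.pair_id] = float(
            np.mean(xi[~is_case] < xj[~is_case])
        )
    return matrix, labels, truth


def monotone_transform(matrix: pd.DataFrame, kind: str, slope: float = 2.0,
                       intercept: float = 5.0) -> pd.DataFrame:
    """Apply a strictly increasing map per sample (invariance test harness).

    ``log2`` requires positive values; ``affine_positive`` uses
    ``slope * x + intercept`` with slope > 0; ``rank`` replaces each
    sample's values by their within-sample ranks (average ranks on ties,
    which preserves every strict ordering and every tie).
    """
    values = matrix.to_numpy(dtype=float)
    if kind == "log2":
        if (values <= 0).any():
            raise ValueError("log2 transform requires strictly positive values")
        out = np.log2(values)
    elif kind == "affine_positive":
        if slope <= 0:
            raise ValueError(f"affine slope must be positive, got {slope}")
        out = slope * values + intercept
    elif kind == "rank":
        from scipy.stats import rankdata

        out = np.apply_along_axis(rankdata, 0, values)
    else:
        raise ValueError(f"unknown transform {kind!r}; use log2|affine_positive|rank")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
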