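"""Reading and writing expression matrices, labels, gene lists, and signatures.

The canonical in-memory expression container is a :class:`pandas.DataFrame`
with gene (or probe) identifiers on the index and sample identifiers on the
columns.  Only the within-sample ordering of values is ever used downstream,
so the scale (linear intensities, TPM, FPKM, log2) is irrelevant as long as
it is consistent within each sample.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
VALID_CLASSES = (CASE, CONTROL)


class MatrixFormatError(ValueError):
    """Raised when an expression-matrix file cannot be parsed or validated."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the frame.

    Gene ids and sample ids must be unique and every value must be finite.
    """
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise MatrixFormatError(
            f"duplicate gene/probe identifiers: {dups[:5]}"
            " (supply a probe-to-gene map to collapse_probes)"
        )
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate sample identifiers: {dups[:5]}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise MatrixFormatError("matrix body is not numeric")
    if not np.isfinite(values).all():
        rows, cols = np.where(~np.isfinite(values))
        gene = matrix.index[rows[0]]
        sample = matrix.columns[cols[0]]
        raise MatrixFormatError(
            f"non-finite value at gene {gene!r}, sample {sample!r}"
        )
    return matrix


def read_expression_matrix(path: str | Path, genes_in: str = "rows") -> pd.DataFrame:
    """Read a TSV expression matrix (header = sample ids, first column = gene ids).

    Parameters
    ----------
    path
        Tab-separated text file with one header line and a numeric body.
    genes_in
        ``"rows"`` (default, GEO series-matrix convention) or ``"columns"``;
        the returned frame is always oriented genes x samples.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError(f"genes_in must be 'rows' or 'columns', got {genes_in!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        matrix = raw.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        rows, cols = np.where(bad.to_numpy())
        if len(rows):
            r, c = raw.index[rows[0]], raw.columns[cols[0]]
            raise MatrixFormatError(
                f"non-numeric cell {raw.iloc[rows[0], cols[0]]!r} "
                f"at row {r!r}, column {c!r} in {path}"
            ) from None
        raise
    if matrix.isna().to_numpy().any():
        rows, cols = np.where(matrix.isna().to_numpy())
        raise MatrixFormatError(
            f"missing value at row {matrix.index[rows[0]]!r}, "
            f"column {matrix.columns[cols[0]]!r} in {path}"
        )
    if genes_in == "columns":
        matrix = matrix.T
    matrix = matrix.astype(float)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    matrix.index.name = "gene_id"
    return validate_matrix(matrix)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV (round-trips with the reader)."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, class) into a sample -> class Series.

    Classes must be ``case`` / ``control`` (case = diseased, e.g. HCC;
    control = e.g. cirrhosis without HCC).
    """
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if table.shape[1] < 2:
        raise MatrixFormatError(f"label file {path} needs two columns (sample_id, class)")
    labels = pd.Series(
        table.iloc[:, 1].to_numpy(), index=table.iloc[:, 0].astype(str), name="class"
    )
    return validate_labels(labels)


def validate_labels(labels: pd.Series, matrix: pd.DataFrame | None = None) -> pd.Series:
    if labels.index.duplicated().any():
        raise MatrixFormatError("duplicate sample id in labels")
    unknown = set(labels.unique()) - set(VALID_CLASSES)
    if unknown:
        raise MatrixFormatError(
            f"unknown class labels {sorted(unknown)}; expected {VALID_CLASSES}"
        )
    if matrix is not None:
        missing = labels.index.difference(matrix.columns)
        if len(missing):
            raise MatrixFormatError(
                f"labeled samples absent from matrix: {missing.tolist()[:5]}"
            )
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    frame = labels.rename("class").rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to gene level by the arithmetic mean.

    Each output gene row is the per-sample arithmetic mean of all its probe
    rows.  Probes absent from the map are dropped (platform maps are always
    partial); the dropped count is logged.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene map is empty")
    mapped = matrix.index.isin(probe_to_gene)
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_dropped)
    sub = matrix.loc[mapped]
    genes = sub.index.map(lambda p: probe_to_gene[p])
    collapsed = sub.groupby(genes, sort=True).mean()
    collapsed.index.name = "gene_id"
    return validate_matrix(collapsed)


def read_gene_list(path: str | Path, case_insensitive: bool = False) -> set[str]:
    """Read a plain-text gene list (one symbol per line) into a set.

    Blank lines are ignored; duplicates are dropped with a logged count.
    Matching is exact and case-sensitive unless ``case_insensitive`` folds
    symbols to upper case.
    """
    text = Path(path).read_text()
    symbols = [line.strip() for line in text.splitlines() if line.strip()]
    if not symbols:
        raise MatrixFormatError(f"gene list {path} is empty")
    if case_insensitive:
        symbols = [s.upper() for s in symbols]
    unique = set(symbols)
    n_dup = len(symbols) - len(unique)
    if n_dup:
        logger.info("read_gene_list: %d duplicate symbols dropped", n_dup)
    return unique
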