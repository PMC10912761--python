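"""Fixed gene-pair signatures: representation, serialization, builtins,
and individual-level application.

A signature is an ordered list of reversal gene pairs in canonical
orientation (gene_i expressed above gene_j in the case class).  Applying a
signature to a sample uses only that sample's within-gene orderings, so
predictions are identical across platforms and unaffected by any monotone
per-sample transform, and never depend on which other samples are in the
batch.

The built-in ``mRMR_SVM_11`` registry entry is the published 11-pair HCC
diagnostic signature over 18 secreted genes, ranked by mRMR.  It ships as
pairs only — no fitted classifier weights were published — so applying it
requires fitting a classifier on user-supplied (or synthetic) training
cohorts first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classify import TrainedPredictor, predict
from .reo import GenePair, encode_profiles


@dataclass(frozen=True)
class GenePairSignature:
    name: str
    pairs: tuple[GenePair, ...]
    provenance: str = ""

    def __post_init__(self):
        if len(self.pairs) == 0:
            raise ValueError("a signature needs at least one pair")
        unordered = [frozenset(p) for p in self.pairs]
        if len(set(unordered)) != len(unordered):
            raise ValueError("duplicate (unordered) gene pair in signature")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in p}


# Published 11-pair mRMR+SVM early-HCC signature (gene_i higher in HCC).
_MRMR_SVM_11_PAIRS = (
    ("PCOLCE2", "DBH"),
    ("RPLP2", "FCN3"),
    ("THY1", "DPT"),
    ("GDF15", "CHST4"),
    ("PTPRA", "DBH"),
    ("RPLP2", "ADAMTSL2"),
    ("PPIC", "C7"),
    ("EIF2AK1", "F8"),
    ("KDSR", "FCN2"),
    ("PRDX4", "C7"),
    ("KDSR", "ASAH1"),
)

_BUILTINS: dict[str, GenePairSignature] = {
    "mRMR_SVM_11": GenePairSignature(
        name="mRMR_SVM_11",
        pairs=tuple(GenePair(gi, gj) for gi, gj in _MRMR_SVM_11_PAIRS),
        provenance=(
            "11 secreted-gene pairs ranked by mRMR for early HCC diagnosis; "
            "gene_i has higher expression than gene_j in HCC relative to "
            "cirrhosis-without-HCC tissue"
        ),
    ),
}

# The companion 28-pair MRMD+SVM signature was published only in a
# supplementary table; we do not invent its pairs.
_UNAVAILABLE: dict[str, str] = {
    "MRMD_SVM_28": (
        "the 28-pair MRMD+SVM signature is defined in supplementary material "
        "not distributed with this package; load it from a signature TSV via "
        "read_signature() if you have the supplement"
    ),
}


def available_signatures() -> list[str]:
    return sorted(_BUILTINS)


def load_builtin_signature(name: str) -> GenePairSignature:
    """Return a packaged signature by name.

    Raises ``KeyError`` listing the available fixtures for unknown names,
    with a dedicated message for registered-but-unavailable placeholders.
    """
    if name in _BUILTINS:
        return _BUILTINS[name]
    if name in _UNAVAILABLE:
        raise KeyError(f"signature {name!r} unavailable: {_UNAVAILABLE[name]}")
    raise KeyError(
        f"unknown signature {name!r}; available: {available_signatures()}"
    )


def read_signature(path: str | Path, name: str | None = None) -> GenePairSignature:
    """Read a signature from TSV (rank, gene_i, gene_j) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return GenePairSignature(
            name=data.get("name", path.stem),
            pairs=tuple(GenePair(p["gene_i"], p["gene_j"]) for p in data["pairs"]),
            provenance=data.get("provenance", ""),
        )
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame = frame.sort_values("rank", key=lambda s: s.astype(int))
    return GenePairSignature(
        name=name or path.stem,
        pairs=tuple(GenePair(gi, gj) for gi, gj in zip(frame["gene_i"], frame["gene_j"])),
    )


def write_signature(sig: GenePairSignature, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "name": sig.name,
            "provenance": sig.provenance,
            "pairs": [
                {"rank": r, "gene_i": p.gene_i, "gene_j": p.gene_j}
                for r, p in enumerate(sig.pairs, start=1)
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    frame = pd.DataFrame(
        {
            "rank": range(1, len(sig.pairs) + 1),
            "gene_i": [p.gene_i for p in sig.pairs],
            "gene_j": [p.gene_j for p in sig.pairs],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def apply_signature(
    matrix: pd.DataFrame,
    sig: GenePairSignature,
    predictor: TrainedPredictor,
) -> tuple[pd.Series, pd.Series]:
    """Encode samples against the signature and predict, one sample at a time.

    The predictor must have been fitted on exactly the signature's pairs in
    order.  Genes absent from the matrix encode as -1, so cross-platform
    matrices with partial gene coverage still yield a defined prediction.
    """
    if [p.pair_id for p in predictor.features] != [p.pair_id for p in sig.pairs]:
        raise ValueError(
            "predictor feature list does not match the signature's pairs "
            f"({predictor.feature_ids[:3]}... vs {[p.pair_id for p in sig.pairs[:3]]}...)"
        )
    encoded = encode_profiles(matrix, list(sig.pairs))
    return predict(predictor, encoded)


def fit_signature_predictor(
    sig: GenePairSignature,
    training_matrix: pd.DataFrame,
    training_labels: pd.Series,
    spec=None,
) -> TrainedPredictor:
    """Fit a classifier for a fixed signature on a training cohort."""
    from .classify import ClassifierSpec, train_classifier

    if spec is None:
        spec = ClassifierSpec.make("svm_rbf")
    encoded = encode_profiles(training_matrix, list(sig.pairs))
    return train_classifier(encoded, training_labels, spec, features=list(sig.pairs))
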