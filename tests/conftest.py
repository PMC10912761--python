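import numpy as np
import pandas as pd
import pytest

from reopair.classify import DEFAULT_SEED
from reopair.reo import EncodedMatrix, GenePair
from reopair.synthdata import SimulationParams, generate_cohorts


@pytest.fixture
def tiny_matrix():
    """4 genes x 4 samples with a clean (g1, g2) reversal between classes."""
    data = {
        "c1": [5.0, 1.0, 3.0, 2.0],
        "c2": [6.0, 2.0, 3.5, 2.5],
        "k1": [1.0, 5.0, 3.0, 2.0],
        "k2": [2.0, 6.0, 3.5, 2.5],
    }
    return pd.DataFrame(data, index=["g1", "g2", "g3", "g4"])


@pytest.fixture
def tiny_labels():
    return pd.Series(
        ["case", "case", "control", "control"],
        index=pd.Index(["c1", "c2", "k1", "k2"], name="sample_id"),
        name="class",
    )


@pytest.fixture(scope="session")
def clean_cohorts():
    """Planted cohorts at stability 1.0: 11 pairs, 200 background genes, 100/50."""
    params = SimulationParams(
        n_background_genes=200,
        n_planted_pairs=11,
        n_case=100,
        n_control=50,
        stability_case=1.0,
        stability_control=1.0,
        seed=DEFAULT_SEED,
    )
    return generate_cohorts(params)


def make_encoded(codes: np.ndarray, pair_names=None, sample_names=None) -> EncodedMatrix:
    """Build an EncodedMatrix directly from a code array (tests only)."""
    codes = np.asarray(codes, dtype=np.int8)
    k, n = codes.shape
    if pair_names is None:
        pair_names = [(f"g{i}", f"h{i}") for i in range(k)]
    pairs = [GenePair(a, b) for a, b in pair_names]
    if sample_names is None:
        sample_names = [f"s{j}" for j in range(n)]
    frame = pd.DataFrame(codes, index=[p.pair_id for p in pairs], columns=sample_names)
    return EncodedMatrix(pairs=pairs, codes=frame)


def binary_labels(t, sample_names=None) -> pd.Series:
    t = np.asarray(t)
    if sample_names is None:
        sample_names = [f"s{j}" for j in range(len(t))]
    return pd.Series(
        np.where(t == 1, "case", "control"),
        index=pd.Index(sample_names, name="sample_id"),
        name="class",
    )
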