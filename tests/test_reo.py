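"""Stable-pair mining, reversal detection, filtering and ternary encoding,
checked against brute-force enumeration and the monotone-invariance
property that motivates rank-based features."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reopair.reo import (
    GenePair,
    PairState,
    StablePairSet,
    encode_profiles,
    filter_pairs_by_gene_set,
    find_reversal_pairs,
    mine_stable_pairs,
    pair_state,
)
from reopair.synthdata import SimulationParams, generate_cohorts, monotone_transform


def brute_force_stable(matrix: pd.DataFrame, samples, threshold):
    """Independent double loop over all ordered gene pairs and samples."""
    pairs = set()
    genes = list(matrix.index)
    for gi, gj in itertools.permutations(genes, 2):
        count = sum(
            1 for s in samples if matrix.loc[gi, s] > matrix.loc[gj, s]
        )
        if count / len(samples) >= threshold - 1e-12:
            pairs.add(GenePair(gi, gj))
    return pairs


class TestPairState:
    @pytest.mark.parametrize(
        "xi,xj,expected",
        [
            (5.0, 3.0, PairState.GREATER),
            (3.0, 3.0, PairState.TIE),
            (1.0, 2.0, PairState.LESS),
        ],
    )
    def test_strict_comparison(self, xi, xj, expected):
        assert pair_state(xi, xj) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pair_state(float("nan"), 1.0)


class TestMineStablePairs:
    def test_unanimous_ordering(self):
        m = pd.DataFrame(
            {"s1": [5, 1], "s2": [6, 2], "s3": [7, 3], "s4": [8, 4]},
            index=["g1", "g2"],
            dtype=float,
        )
        stable = mine_stable_pairs(m, list(m.columns), threshold=0.85)
        assert stable.pairs == frozenset({GenePair("g1", "g2")})

    def test_threshold_is_inclusive_at_exact_fraction(self):
        # g1 > g2 in exactly 17/20 samples = 0.85: "at least 85%" includes it
        rows = np.ones((2, 20))
        rows[0] = 2.0
        rows[0, :3] = 0.5  # 3 samples where g1 < g2
        m = pd.DataFrame(rows, index=["g1", "g2"], columns=[f"s{i}" for i in range(20)])
        stable = mine_stable_pairs(m, list(m.columns), threshold=0.85)
        assert GenePair("g1", "g2") in stable
        # one fewer concordant sample (16/20 = 0.80) must drop out
        rows[0, 3] = 0.5
        m2 = pd.DataFrame(rows, index=["g1", "g2"], columns=m.columns)
        assert GenePair("g1", "g2") not in mine_stable_pairs(m2, list(m.columns), 0.85)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g, n = rng.integers(3, 9), rng.integers(4, 13)
            m = pd.DataFrame(
                rng.normal(size=(g, n)),
                index=[f"g{i}" for i in range(g)],
                columns=[f"s{j}" for j in range(n)],
            )
            threshold = rng.choice([0.6, 0.75, 0.85, 1.0])
            mined = mine_stable_pairs(m, list(m.columns), threshold).pairs
            assert mined == brute_force_stable(m, list(m.columns), threshold)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.normal(size=(6, 10)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(10)],
        )
        strict = mine_stable_pairs(m, list(m.columns), threshold=1.0).pairs
        for thr in (0.95, 0.85, 0.7, 0.6):
            assert strict <= mine_stable_pairs(m, list(m.columns), thr).pairs

    def test_at_most_one_orientation(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.normal(size=(5, 9)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(9)],
        )
        pairs = mine_stable_pairs(m, list(m.columns), 0.6).pairs
        assert not any(p.swapped() in pairs for p in pairs)

    def test_empty_or_unknown_samples_error(self, tiny_matrix):
        with pytest.raises(ValueError):
            mine_stable_pairs(tiny_matrix, [], 0.85)
        with pytest.raises(ValueError, match="unknown sample"):
            mine_stable_pairs(tiny_matrix, ["nope"], 0.85)


class TestFindReversalPairs:
    @staticmethod
    def _stable(pairs, label):
        return StablePairSet(label, 0.85, frozenset(pairs))

    def test_definition(self):
        sc = self._stable({GenePair("a", "b")}, "case")
        sk = self._stable({GenePair("b", "a")}, "control")
        assert set(find_reversal_pairs(sc, sk).pairs) == {GenePair("a", "b")}

    def test_concordant_pairs_excluded(self):
        sc = self._stable({GenePair("a", "b")}, "case")
        sk = self._stable({GenePair("a", "b")}, "control")
        assert len(find_reversal_pairs(sc, sk)) == 0

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = rng.integers(3, 9)
            m = pd.DataFrame(
                rng.normal(size=(g, 12)),
                index=[f"g{i}" for i in range(g)],
                columns=[f"s{j}" for j in range(12)],
            )
            case, ctrl = list(m.columns[:6]), list(m.columns[6:])
            sc = mine_stable_pairs(m, case, 0.66, "case")
            sk = mine_stable_pairs(m, ctrl, 0.66, "control")
            got = set(find_reversal_pairs(sc, sk).pairs)
            expected = {
                p
                for p in brute_force_stable(m, case, 0.66)
                if p.swapped() in brute_force_stable(m, ctrl, 0.66)
            }
            assert got == expected


class TestFilterPairs:
    def setup_method(self):
        self.pairs = find_reversal_pairs(
            StablePairSet("case", 0.85, frozenset({GenePair("a", "b"), GenePair("a", "c")})),
            StablePairSet("control", 0.85, frozenset({GenePair("b", "a"), GenePair("c", "a")})),
        )

    def test_both_genes_required(self):
        kept = filter_pairs_by_gene_set(self.pairs, {"a", "b"})
        assert set(kept.pairs) == {GenePair("a", "b")}

    def test_superset_is_identity(self):
        kept = filter_pairs_by_gene_set(self.pairs, {"a", "b", "c", "z"})
        assert set(kept.pairs) == set(self.pairs.pairs)

    def test_empty_whitelist_empties(self):
        assert len(filter_pairs_by_gene_set(self.pairs, set())) == 0


class TestEncodeProfiles:
    def test_codes(self, tiny_matrix):
        enc = encode_profiles(tiny_matrix, [GenePair("g1", "g2")])
        # case samples: g1 > g2 -> 0; control samples: g1 < g2 -> 1
        assert enc.codes.loc["g1|g2"].tolist() == [0, 0, 1, 1]

    def test_missing_gene_is_minus_one_everywhere(self, tiny_matrix):
        enc = encode_profiles(tiny_matrix, [GenePair("g1", "zz")])
        assert (enc.codes.loc["g1|zz"] == -1).all()

    def test_tie_is_minus_one(self):
        m = pd.DataFrame({"s1": [3.0, 3.0]}, index=["a", "b"])
        enc = encode_profiles(m, [GenePair("a", "b")])
        assert enc.codes.loc["a|b", "s1"] == -1

    def test_code_fractions_sum_to_one(self, clean_cohorts):
        matrix, _, truth = clean_cohorts
        enc = encode_profiles(matrix, truth.planted_pairs)
        for pid in enc.codes.index:
            row = enc.codes.loc[pid]
            fracs = [(row == c).mean() for c in (0, 1, -1)]
            assert sum(fracs) == pytest.approx(1.0)

    def test_tsv_round_trip(self, tiny_matrix, tmp_path):
        enc = encode_profiles(tiny_matrix, [GenePair("g1", "g2"), GenePair("g3", "g4")])
        path = tmp_path / "enc.tsv"
        enc.to_tsv(path)
        back = type(enc).from_tsv(path)
        pd.testing.assert_frame_equal(
            back.codes, enc.codes, check_dtype=False, check_names=False
        )


class TestMonotoneInvariance:
    """Rank-based features ignore any strictly increasing per-sample map."""

    @pytest.mark.parametrize("kind", ["log2", "affine_positive", "rank"])
    def test_mining_and_encoding_bit_identical(self, kind):
        params = SimulationParams(
            n_background_genes=20, n_planted_pairs=3, n_case=15, n_control=10,
            stability_case=0.9, stability_control=0.9, seed=77,
        )
        matrix, labels, truth = generate_cohorts(params)
        transformed = monotone_transform(matrix, kind)
        case = labels.index[labels == "case"].tolist()
        a = mine_stable_pairs(matrix, case, 0.85).pairs
        b = mine_stable_pairs(transformed, case, 0.85).pairs
        assert a == b
        e1 = encode_profiles(matrix, truth.planted_pairs).codes
        e2 = encode_profiles(transformed, truth.planted_pairs).codes
        assert (e1.to_numpy() == e2.to_numpy()).all()

    @given(slope=st.floats(0.1, 50), intercept=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_property(self, slope, intercept):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(
            rng.normal(size=(5, 8)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(8)],
        )
        t = m * slope + intercept
        assert (
            mine_stable_pairs(m, list(m.columns), 0.75).pairs
            == mine_stable_pairs(t, list(m.columns), 0.75).pairs
        )


class TestPlantedRecovery:
    def test_perfect_stability_recovers_exactly_the_planted_set(self, clean_cohorts):
        matrix, labels, truth = clean_cohorts
        case = labels.index[labels == "case"].tolist()
        ctrl = labels.index[labels == "control"].tolist()
        sc = mine_stable_pairs(matrix, case, 0.85, "case")
        sk = mine_stable_pairs(matrix, ctrl, 0.85, "control")
        rev = find_reversal_pairs(sc, sk)
        assert set(rev.pairs) == set(truth.planted_pairs)
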