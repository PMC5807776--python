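import numpy as np
import pandas as pd
import pytest
from fractions import Fraction
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from heiferseq import (
    pair_count,
    ratio_features,
    tsp_classify,
    tsp_permutation_p,
    tsp_scan,
)
from heiferseq.tsp import TSPPair


def _df(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def brute_force_rank(expr: pd.DataFrame, labels, top_k):
    """Independent exact-arithmetic double-loop TSP oracle."""
    x = expr.to_numpy(float)
    ids = list(expr.index.astype(str))
    lab = np.asarray(labels)
    uniq = list(dict.fromkeys(lab.tolist()))
    m1, m2 = lab == uniq[0], lab == uniq[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    ranks = rankdata(x, axis=0)
    recs = []
    for i in range(x.shape[0]):
        for j in range(i + 1, x.shape[0]):
            less = x[i] < x[j]
            f1 = Fraction(int(less[m1].sum()), n1)
            f2 = Fraction(int(less[m2].sum()), n2)
            di = Fraction(ranks[i][m1].sum()) / n1 - Fraction(ranks[i][m2].sum()) / n2
            dj = Fraction(ranks[j][m1].sum()) / n1 - Fraction(ranks[j][m2].sum()) / n2
            recs.append((abs(f1 - f2), abs(di - dj), ids[i], ids[j]))
    recs.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    return recs[:top_k]


class TestScan:
    def test_perfect_reversal_scores_one(self):
        x = _df([[1, 1, 1, 9, 9, 9], [5, 5, 5, 5, 5, 5]])
        scan = tsp_scan(x, np.array(["a"] * 3 + ["b"] * 3), top_k=1)
        assert scan.max_delta == 1.0
        assert scan.pairs[0].delta == 1.0

    def test_constant_matrix_all_deltas_zero(self):
        scan = tsp_scan(_df(np.ones((4, 6))), np.array(["a"] * 3 + ["b"] * 3))
        assert scan.max_delta == 0.0
        assert all(p.delta == 0.0 for p in scan.pairs)

    def test_ordered_pair_accounting(self):
        scan = tsp_scan(_df(np.arange(30).reshape(5, 6)),
                        np.array(["a"] * 3 + ["b"] * 3))
        assert scan.n_pairs_evaluated == pair_count(5) == 20

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_scan_equals_bruteforce_oracle(self, data):
        G = data.draw(st.integers(2, 8))
        S = data.draw(st.integers(4, 10))
        n1 = data.draw(st.integers(2, S - 2))
        seed = data.draw(st.integers(0, 10_000))
        block = data.draw(st.integers(1, 8))
        rng = np.random.default_rng(seed)
        x = _df(rng.integers(0, 5, size=(G, S)))  # integer values force ties
        labels = np.array(["a"] * n1 + ["b"] * (S - n1))
        k = min(10, G * (G - 1) // 2)
        scan = tsp_scan(x, labels, top_k=k, block_size=block)
        oracle = brute_force_rank(x, labels, k)
        got = [
            (Fraction(p.delta).limit_denominator(10**6),
             Fraction(p.gamma).limit_denominator(10**6),
             *sorted((p.gene_i, p.gene_j)))
            for p in scan.pairs
        ]
        expected = [(d, g, *sorted((a, b))) for d, g, a, b in oracle]
        assert got == expected

    def test_invariant_to_monotone_within_sample_transforms(self, rng):
        x = _df(rng.lognormal(1, 1, size=(12, 9)))
        labels = np.array(["a"] * 5 + ["b"] * 4)
        base = tsp_scan(x, labels, top_k=8)
        scale = rng.uniform(0.5, 3.0, size=9)
        shift = rng.uniform(0.0, 2.0, size=9)
        for transform in (np.log, lambda v: v * scale + shift):
            t = tsp_scan(_df(transform(x.to_numpy())), labels, top_k=8)
            assert [(p.gene_i, p.gene_j, p.delta) for p in t.pairs] == [
                (p.gene_i, p.gene_j, p.delta) for p in base.pairs
            ]

    def test_rejects_bad_inputs(self, rng):
        x = _df(rng.normal(size=(4, 6)))
        with pytest.raises(ValueError, match="at least 2 samples"):
            tsp_scan(x, np.array(["a", "b", "b", "b", "b", "b"]))
        x.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            tsp_scan(x, np.array(["a"] * 3 + ["b"] * 3))


class TestPermutationP:
    def test_floor_is_one_over_nperm_plus_one(self, rng):
        # a perfect reversal pair among fillers; 8v8 so label recreation is rare
        n = 8
        x = np.vstack([
            np.r_[np.full(n, 1.0), np.full(n, 9.0)],
            np.full(2 * n, 5.0),
            rng.lognormal(4, 0.2, size=(6, 2 * n)),
        ])
        labels = np.array(["a"] * n + ["b"] * n)
        p = tsp_permutation_p(_df(x), labels, n_perm=50, seed=123)
        assert p == pytest.approx(1 / 51)

    def test_p_never_zero(self, rng):
        x = _df(rng.normal(size=(5, 8)))
        p = tsp_permutation_p(x, np.array(["a"] * 4 + ["b"] * 4), n_perm=30, seed=0)
        assert p >= 1 / 31

    def test_zero_permutations_rejected(self, rng):
        x = _df(rng.normal(size=(5, 8)))
        with pytest.raises(ValueError, match="n_perm"):
            tsp_permutation_p(x, np.array(["a"] * 4 + ["b"] * 4), n_perm=0)

    def test_null_calibration(self):
        """With labels independent of expression the p-value is not
        anti-conservative: few null datasets reach small p."""
        hits = 0
        for k in range(50):
            rng = np.random.default_rng(9000 + k)
            x = _df(rng.lognormal(2, 1, size=(10, 10)))
            labels = np.array(["a"] * 5 + ["b"] * 5)
            if tsp_permutation_p(x, labels, n_perm=200, seed=k) <= 0.1:
                hits += 1
        assert hits <= 5


class TestClassify:
    def test_perfect_pair_classifies_training_data(self):
        x = _df([[1, 1, 1, 9, 9, 9], [5, 5, 5, 5, 5, 5]])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        scan = tsp_scan(x, labels, top_k=1)
        pred, acc, overall = tsp_classify(x, scan.pairs, labels, classes=scan.classes)
        assert (pred == labels).all()
        assert acc == {"a": 1.0, "b": 1.0}
        assert overall == 1.0

    def test_all_ties_abstain_to_larger_class(self):
        x = _df(np.ones((2, 5)))
        pair = [TSPPair("g0", "g1", 0.0, 0.0, 0.0, 0.0)]
        pred, _, _ = tsp_classify(x, pair, classes=("a", "b"), class_sizes=(2, 3))
        assert (pred == "b").all()
        # a class-size tie resolves to class 1
        pred, _, _ = tsp_classify(x, pair, classes=("a", "b"), class_sizes=(3, 3))
        assert (pred == "a").all()

    def test_missing_gene_is_error(self, rng):
        x = _df(rng.normal(size=(3, 4)))
        with pytest.raises(KeyError):
            tsp_classify(x, [TSPPair("g0", "gX", 1, 1, 1, 0)])


class TestRatioFeatures:
    def test_arithmetic(self):
        x = _df([[3.0, 1.0], [1.0, 1.0]])
        pair = [TSPPair("g0", "g1", 1.0, 1.0, 1.0, 0.0)]
        feats = ratio_features(x, pair, epsilon=1.0)
        assert feats.iloc[0, 0] == pytest.approx(1.0)   # log2((3+1)/(1+1))
        assert feats.iloc[0, 1] == pytest.approx(0.0)   # equal FPKM

    def test_orientation_swap_negates_rows(self, rng):
        x = _df(rng.lognormal(1, 1, size=(6, 7)))
        fwd = [TSPPair("g0", "g3", 0.5, 1.0, 0.7, 0.2)]
        rev = [TSPPair("g3", "g0", 0.5, 1.0, 0.7, 0.2)]
        a = ratio_features(x, fwd).to_numpy()
        b = ratio_features(x, rev).to_numpy()
        assert np.allclose(a, -b)

    def test_empty_pair_list_rejected(self, rng):
        with pytest.raises(ValueError):
            ratio_features(_df(rng.normal(size=(2, 3))), [])
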