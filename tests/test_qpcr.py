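import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heiferseq import (
    SimConfig,
    concordance,
    delta_ct,
    exact_nb_test,
    group_ttest_dct,
    reference_stability_check,
    simulate_counts,
    simulate_qpcr,
    ttest_power,
)


def _long_table(ct: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    rows = [
        (sid, gene, vals[k])
        for gene, vals in ct.items()
        for k, sid in enumerate(samples)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "ct"])


SAMPLES = [f"s{i}" for i in range(4)]


class TestDeltaCT:
    def test_arithmetic(self):
        tab = _long_table({"REF": [20.0] * 4, "T": [25.0, 20.0, 22.0, 18.0]}, SAMPLES)
        dct = delta_ct(tab, "REF")
        assert list(dct.loc["T", SAMPLES]) == [5.0, 0.0, 2.0, -2.0]

    def test_missing_reference_measurement_is_error(self):
        tab = _long_table({"REF": [20.0] * 4, "T": [25.0] * 4}, SAMPLES)
        tab = tab[~((tab.gene_id == "REF") & (tab.sample_id == "s0"))]
        with pytest.raises(ValueError, match="reference"):
            delta_ct(tab, "REF")


class TestReferenceStability:
    def test_identical_cts_pass(self):
        tab = _long_table({"REF": [20.0] * 4}, SAMPLES)
        p, ok = reference_stability_check(tab, "REF", ["a", "a", "b", "b"])
        assert p == 1.0 and ok

    def test_shifted_reference_fails(self):
        rng = np.random.default_rng(0)
        fails = 0
        for k in range(500):
            ct = np.r_[rng.normal(20, 0.2, 6), rng.normal(22, 0.2, 6)]
            tab = _long_table({"REF": list(ct)}, [f"s{i}" for i in range(12)])
            _, ok = reference_stability_check(tab, "REF", ["a"] * 6 + ["b"] * 6)
            fails += int(not ok)
        assert fails >= 495

    def test_null_pass_rate_matches_threshold(self):
        rng = np.random.default_rng(1)
        passes = 0
        for k in range(600):
            ct = rng.normal(20, 0.5, 12)
            tab = _long_table({"REF": list(ct)}, [f"s{i}" for i in range(12)])
            _, ok = reference_stability_check(tab, "REF", ["a"] * 6 + ["b"] * 6)
            passes += int(ok)
        assert passes / 600 == pytest.approx(0.5, abs=0.07)


class TestGroupTTest:
    def test_identical_groups(self):
        dct = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["T"], columns=SAMPLES)
        res = group_ttest_dct(dct, ["a", "a", "b", "b"])
        assert res.loc["T", "p"] == 1.0
        assert res.loc["T", "fold_change"] == 1.0
        assert not res.loc["T", "significant"]

    def test_matches_textbook_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        dct = pd.DataFrame([np.r_[a, b]], index=["T"],
                           columns=[f"s{i}" for i in range(12)])
        res = group_ttest_dct(dct, ["g1"] * 6 + ["g2"] * 6)
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2))
        tstat = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 6))
        p = 2 * stats.t.sf(abs(tstat), 10)
        assert res.loc["T", "p"] == pytest.approx(p, abs=1e-12)

    def test_significance_flag_tracks_alpha(self, rng):
        dct = pd.DataFrame(rng.normal(size=(20, 12)),
                           columns=[f"s{i}" for i in range(12)])
        res = group_ttest_dct(dct, ["a"] * 6 + ["b"] * 6, alpha=0.1)
        assert (res["significant"] == (res["p"] <= 0.1)).all()

    def test_fold_changes_reciprocal_under_group_swap(self, rng):
        dct = pd.DataFrame(rng.normal(size=(5, 12)),
                           columns=[f"s{i}" for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        fwd = group_ttest_dct(dct, groups, group_order=("a", "b"))
        rev = group_ttest_dct(dct, groups, group_order=("b", "a"))
        assert np.allclose(fwd["fold_change"] * rev["fold_change"], 1.0)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert ttest_power(6, 0.0, 0.1, "one") == pytest.approx(0.1, abs=1e-9)

    def test_monotonicity(self):
        assert ttest_power(8, 1, 0.1) > ttest_power(6, 1, 0.1)
        assert ttest_power(6, 1.5, 0.1) > ttest_power(6, 1.0, 0.1)
        assert ttest_power(6, 1, 0.2) > ttest_power(6, 1, 0.1)
        assert ttest_power(6, 1, 0.1, "two") < ttest_power(6, 1, 0.1, "one")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ttest_power(1, 1, 0.1)
        with pytest.raises(ValueError):
            ttest_power(6, 1, 0.1, sided="three")


class TestConcordance:
    IDX = list("abcdef")

    def test_identical_and_reversed_rankings(self):
        x = pd.Series([1, 2, 3, 4, 5, 6.0], index=self.IDX)
        rho, _ = concordance(x, x * 3 + 1)
        assert rho == pytest.approx(1.0)
        rho, _ = concordance(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_enumeration(self, rng):
        x = pd.Series(rng.normal(size=6), index=self.IDX)
        y = pd.Series(x.to_numpy() + rng.normal(0, 0.8, 6), index=self.IDX)
        rho, p = concordance(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        for perm in itertools.permutations(range(6)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 720, abs=1e-12)

    def test_requires_three_shared_genes(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="shared"):
            concordance(x, x)

    def test_qpcr_and_rnaseq_fold_changes_agree_on_shared_truth(self):
        """Both assays estimate the same planted fold changes, so their
        rankings correlate strongly (mean Spearman > 0.7 over replicates)."""
        rhos = []
        for k in range(20):
            cfg = SimConfig(n_genes=250, n_de_genes=6, de_log2fc_range=(0.5, 2.5),
                            library_size_range=(40_000, 80_000), seed=3000 + k)
            matrix, samples, _, truth = simulate_counts(cfg)
            genes = sorted(truth.de_genes)
            reference = next(
                g for g in truth.group_means.index if g not in truth.de_genes
            )
            qtab = simulate_qpcr(truth, samples, genes, reference,
                                 noise_sd=0.2, seed=k)
            dct = delta_ct(qtab, reference)
            outcome = samples.set_index("sample_id").loc[dct.columns, "outcome"]
            qres = group_ttest_dct(dct, outcome.to_numpy())
            rna = exact_nb_test(matrix, samples["outcome"].to_numpy())
            rho, _ = concordance(
                qres["fold_change"], 2.0 ** rna.loc[genes, "log2fc"]
            )
            rhos.append(rho)
        assert np.mean(rhos) > 0.7
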