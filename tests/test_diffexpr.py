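import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heiferseq import (
    SimConfig,
    consensus_deg,
    de_table,
    efdr,
    estimate_dispersions,
    exact_nb_test,
    median_of_ratios_size_factors,
    simulate_counts,
    wald_nb_test,
)


def _df(arr):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


LAB44 = np.array(["a"] * 4 + ["b"] * 4)
ONES8 = pd.Series(1.0, index=[f"s{j}" for j in range(8)])


class TestDispersions:
    def test_constant_gene_moment_estimate_is_zero(self):
        counts = _df(np.tile([[7], [3]], (1, 8)))
        d = estimate_dispersions(counts, LAB44, method="moments",
                                 size_factors=ONES8)
        assert (d == 0).all()

    def test_poisson_counts_give_near_zero_common(self):
        m, s, _, _ = simulate_counts(
            SimConfig(n_genes=1000, dispersion=0.0, seed=31,
                      library_size_range=(50_000, 100_000))
        )
        d = estimate_dispersions(m, s["outcome"].to_numpy(), method="cml_common")
        assert d.iloc[0] < 0.01

    def test_common_dispersion_recovery(self):
        estimates = []
        for k in range(20):
            m, s, _, _ = simulate_counts(
                SimConfig(n_genes=500, dispersion=0.2, seed=600 + k,
                          library_size_range=(50_000, 100_000))
            )
            d = estimate_dispersions(m, s["outcome"].to_numpy(), method="cml_common")
            estimates.append(d.iloc[0])
        assert np.mean(estimates) == pytest.approx(0.2, rel=0.25)

    def test_single_sample_group_rejected(self):
        counts = _df(np.ones((3, 3)))
        with pytest.raises(ValueError):
            estimate_dispersions(counts, np.array(["a", "b", "b"]))


class TestExactEngine:
    def _poisson_fixture(self, seed=1, max_total=30):
        rng = np.random.default_rng(seed)
        counts = _df(rng.integers(0, max_total // 8, size=(40, 8)))
        # equalize library sizes so the conditional law is exactly binomial
        counts.iloc[0] += (counts.sum(0).max() - counts.sum(0)).to_numpy()
        return counts

    @staticmethod
    def _binomial_two_sided(s1, t, p1):
        pmf = stats.binom.pmf(np.arange(t + 1), t, p1)
        return pmf[pmf <= pmf[s1] * (1 + 1e-9)].sum()

    def test_poisson_limit_equals_conditional_binomial(self):
        counts = self._poisson_fixture()
        res = exact_nb_test(
            counts, LAB44, factors=ONES8,
            dispersions=pd.Series(0.0, index=counts.index),
            group_order=("a", "b"),
        )
        for g in counts.index:
            s1 = int(counts.loc[g][:4].sum())
            t = int(counts.loc[g].sum())
            assert res.loc[g, "p"] == pytest.approx(
                self._binomial_two_sided(s1, t, 0.5), rel=1e-9
            )

    def test_label_swap_symmetry(self):
        counts = self._poisson_fixture(seed=4)
        disp = pd.Series(0.15, index=counts.index)
        fwd = exact_nb_test(counts, LAB44, ONES8, disp, group_order=("a", "b"))
        rev = exact_nb_test(counts, LAB44, ONES8, disp, group_order=("b", "a"))
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])

    def test_identical_group_means_give_p_one_and_zero_fc(self):
        counts = _df(np.tile([[40], [7]], (1, 8)))
        res = exact_nb_test(
            counts, LAB44, ONES8, pd.Series(0.1, index=counts.index),
            group_order=("a", "b"),
        )
        assert np.allclose(res["p"], 1.0)
        assert np.allclose(res["log2fc"], 0.0)

    def test_power_on_planted_fourfold_gene(self):
        """Planted 4-fold change, baseline mean 200, phi=0.1, 6v6: each row
        is an independent replicate of the same gene."""
        rng = np.random.default_rng(77)
        n_rep = 200
        r = 1 / 0.1
        mu = np.concatenate([np.full(6, 100.0), np.full(6, 400.0)])
        counts = rng.negative_binomial(r, r / (r + mu), size=(n_rep, 12))
        counts = _df(counts)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        # every row carries the same planted change, so the stable-background
        # assumption of data-driven normalization does not apply here: supply
        # factors that fix equal effective library sizes instead
        lib = counts.sum(0).to_numpy(float)
        f = 1.0 / lib
        factors = pd.Series(f / np.exp(np.mean(np.log(f))), index=counts.columns)
        res = exact_nb_test(
            counts, labels,
            factors=factors,
            dispersions=pd.Series(0.1, index=counts.index),
            group_order=("a", "b"),
        )
        assert (res["p"] <= 0.01).mean() >= 0.90
        assert res["log2fc"].median() == pytest.approx(2.0, abs=0.3)


class TestWaldEngine:
    def test_identical_columns_give_unit_size_factors(self):
        counts = _df(np.tile([[10], [30], [5]], (1, 6)))
        assert np.allclose(median_of_ratios_size_factors(counts), 1.0)

    def test_agrees_with_exact_engine_on_large_mean_poisson(self):
        m, s, _, _ = simulate_counts(
            SimConfig(n_genes=2000, dispersion=0.0, seed=55,
                      mean_log_sd=0.5, library_size_range=(1_000_000, 1_600_000))
        )
        labels = s["outcome"].to_numpy()
        disp = estimate_dispersions(m, labels)
        ex = exact_nb_test(m, labels, dispersions=disp)
        wa = wald_nb_test(m, labels, dispersions=disp)
        rho = stats.spearmanr(ex["p"], wa["p"]).statistic
        assert rho >= 0.95

    def test_fold_changes_of_both_engines_correlate(self):
        """The two engines report near-identical per-gene fold changes."""
        m, s, _, _ = simulate_counts(
            SimConfig(n_genes=1000, n_de_genes=50, de_log2fc_range=(1.0, 2.5),
                      seed=66, library_size_range=(50_000, 100_000))
        )
        res = de_table(m, s["outcome"].to_numpy())
        r = np.corrcoef(res["log2fc"], res["log2fc_wald"])[0, 1]
        assert r > 0.99

    def test_nonconvergence_flag_excludes_gene(self):
        counts = _df([[0, 0, 0, 0, 5, 9, 7, 6], [9, 9, 9, 9, 9, 9, 9, 9]])
        res = wald_nb_test(
            counts, LAB44,
            size_factors=ONES8,
            dispersions=pd.Series(0.1, index=counts.index),
            group_order=("a", "b"),
        )
        assert not res.loc["g0", "converged"]
        assert np.isnan(res.loc["g0", "p"])
        assert np.isfinite(res.loc["g0", "log2fc"])


class TestConsensus:
    def test_rule_requires_both_engines(self):
        res = pd.DataFrame(
            {"p_exact": [0.005, 0.005, 0.02], "p_wald": [0.005, 0.02, 0.005]},
            index=["yes", "no1", "no2"],
        )
        assert consensus_deg(res, 0.01) == {"yes"}

    def test_consensus_never_exceeds_single_engines(self):
        for k in range(3):
            m, s, _, _ = simulate_counts(
                SimConfig(n_genes=800, seed=80 + k,
                          library_size_range=(40_000, 80_000))
            )
            res = de_table(m, s["outcome"].to_numpy())
            n_cons = res["consensus_deg"].sum()
            assert n_cons <= (res["p_exact"] <= 0.01).sum()
            assert n_cons <= (res["p_wald"] <= 0.01).sum()


class TestEFDR:
    def test_empty_observed_set_is_undefined(self):
        m, s, _, _ = simulate_counts(
            SimConfig(n_genes=100, seed=90, library_size_range=(20_000, 40_000))
        )
        est = efdr(m, s["outcome"].to_numpy(), alpha=1e-9, n_perm=20, seed=1)
        assert est.undefined and est.efdr is None and est.n_observed == 0

    def test_zero_permutations_rejected(self, small_counts):
        with pytest.raises(ValueError, match="n_perm"):
            efdr(small_counts, np.array(["a"] * 3 + ["b"] * 3), n_perm=0)

    def test_warns_when_assignments_exhausted(self, small_counts):
        with pytest.warns(UserWarning, match="with replacement"):
            efdr(small_counts, np.array(["a"] * 3 + ["b"] * 3), n_perm=25, seed=0)

    def test_deterministic_under_seed(self):
        m, s, _, _ = simulate_counts(
            SimConfig(n_genes=300, n_de_genes=20, de_log2fc_range=(1.5, 2.5),
                      seed=91, library_size_range=(30_000, 60_000))
        )
        a = efdr(m, s["outcome"].to_numpy(), n_perm=50, seed=5)
        b = efdr(m, s["outcome"].to_numpy(), n_perm=50, seed=5)
        assert a == b

    def test_monotone_in_planted_effect_size(self):
        """eFDR decreases as the planted effect strengthens (3-point grid)."""
        vals = []
        for fc in (0.4, 1.2, 2.5):
            m, s, _, _ = simulate_counts(
                SimConfig(n_genes=800, n_de_genes=40,
                          de_log2fc_range=(fc, fc), seed=92,
                          library_size_range=(40_000, 80_000))
            )
            est = efdr(m, s["outcome"].to_numpy(), n_perm=150, seed=6)
            vals.append(1.0 if est.undefined else est.efdr)
        assert vals[0] >= vals[1] >= vals[2]
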