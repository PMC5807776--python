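"""qPCR validation statistics: delta-CT, group t-tests, power, concordance.

CT values (cycle thresholds) are normalized against a reference gene:
dCT = CT_target - CT_reference per sample. The between-group difference
ddCT converts to a fold change of 2^(-ddCT), assuming amplification
efficiency 2 per cycle. Group comparisons use two-sample t-tests at
alpha = 0.1; the power of that design is computed from the noncentral t.
Concordance between qPCR and RNA-seq fold changes is Spearman's rank
correlation with an exact permutation p-value for small gene panels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _pivot_ct(table: pd.DataFrame) -> pd.DataFrame:
    if table.duplicated(["sample_id", "gene_id"]).any():
        raise ValueError("more than one CT per sample x gene")
    return table.pivot(index="gene_id", columns="sample_id", values="ct")


def delta_ct(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-sample dCT = CT_target - CT_reference for every non-reference gene."""
    wide = _pivot_ct(table)
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    ref = wide.loc[reference_gene]
    if ref.isna().any():
        missing = ref.index[ref.isna()].tolist()
        raise ValueError(f"reference gene not measured in samples {missing}")
    return wide.drop(index=reference_gene).sub(ref, axis=1)


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 measurements")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0  # identical constants: no evidence of difference
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def reference_stability_check(
    table: pd.DataFrame,
    reference_gene: str,
    groups,
    threshold: float = 0.5,
    welch: bool = False,
) -> tuple[float, bool]:
    """t-test of the reference gene's CT between groups; pass iff p > threshold."""
    wide = _pivot_ct(table)
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    ref = wide.loc[reference_gene]
    if isinstance(groups, pd.Series):
        g = groups.reindex(ref.index)
    else:
        # a plain sequence is aligned with the table's sample order, which the
        # pivot may have re-sorted lexicographically
        order = list(dict.fromkeys(table["sample_id"]))
        if len(groups) != len(order):
            raise ValueError("one group label per sample required")
        g = pd.Series(list(groups), index=order).reindex(ref.index)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    labels = list(dict.fromkeys(g.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = ref[g.to_numpy() == labels[0]].to_numpy(dtype=float)
    b = ref[g.to_numpy() == labels[1]].to_numpy(dtype=float)
    p = _two_sample_t(a, b, welch)
    return p, bool(p > threshold)


def group_ttest_dct(
    dct: pd.DataFrame,
    groups,
    alpha: float = 0.1,
    group_order=None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test on dCT values.

    Returns mean ddCT (second group minus first), fold change 2^(-ddCT),
    the p-value (pooled variance by default, Welch optional) and the
    significance flag at ``alpha``.
    """
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if group_order is not None:
        labels = list(group_order)
    m1, m2 = g == labels[0], g == labels[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for gene, vals in dct.iterrows():
        a = vals.to_numpy(dtype=float)[m1]
        b = vals.to_numpy(dtype=float)[m2]
        ddct = float(b.mean() - a.mean())
        p = _two_sample_t(a, b, welch)
        rows.append(
            {
                "gene_id": gene,
                "ddct": ddct,
                "fold_change": 2.0 ** (-ddct),
                "p": p,
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def ttest_power(
    n_per_group: int = 6,
    effect_size: float = 1.0,
    alpha: float = 0.1,
    sided: str = "one",
) -> float:
    """Power of the two-sample t-test from the noncentral t distribution.

    df = 2n - 2 and noncentrality d * sqrt(n/2). One-sided by default.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    nc = effect_size * np.sqrt(n_per_group / 2.0)
    if sided == "one":
        tc = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tc, df, nc))
    if sided == "two":
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    raise ValueError("sided must be 'one' or 'two'")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all n! orderings of one rank vector; rho is the Pearson
    correlation of the (possibly tied) ranks, computed in chunks.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    count = 0
    total = 0
    it = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(it, 100_000))
        if not chunk:
            break
        perms = np.asarray(chunk)
        rhos = (cy[perms] @ cx) / denom
        count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
        total += len(chunk)
    return count / total


def concordance(fc_qpcr: pd.Series, fc_rnaseq: pd.Series) -> tuple[float, float]:
    """Spearman correlation between qPCR and RNA-seq fold changes.

    Exact two-sided permutation p for panels of <= 10 genes, the usual
    t-approximation above that. Requires >= 3 shared genes.
    """
    shared = fc_qpcr.index.intersection(fc_rnaseq.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = fc_qpcr.reindex(shared).to_numpy(dtype=float)
    y = fc_rnaseq.reindex(shared).to_numpy(dtype=float)
    rho, p_approx = stats.spearmanr(x, y)
    rho = float(rho)
    if len(shared) <= 10:
        return rho, float(_spearman_exact_p(x, y, rho))
    return rho, float(p_approx)
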