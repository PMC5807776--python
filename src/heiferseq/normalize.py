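"""Expression normalization and detection filtering.

CPM and FPKM definitions, the "> 1 CPM in >= 6 samples" detection rule,
trimmed-mean-of-M-values (TMM) between-sample normalization factors, and
the station-set (Venn) partition of detected genes.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix


def _count_df(counts) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def cpm(counts, use_factors: bool = False, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Counts per million: count / (library size x factor) x 1e6.

    With ``use_factors`` off every column of the result sums to exactly 1e6
    (up to float rounding); with TMM factors on, the effective library size
    is library size x factor.
    """
    df = _count_df(counts)
    lib = df.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size for samples {zero}")
    eff = lib
    if use_factors:
        if factors is None:
            raise ValueError("use_factors=True requires factors")
        eff = lib * factors.reindex(df.columns).astype(float)
    vals = df.to_numpy(dtype=float) / eff.to_numpy() * 1e6
    return ExpressionMatrix(pd.DataFrame(vals, index=df.index, columns=df.columns), "CPM")


def detection_filter(counts, cpm_threshold: float = 1.0, min_samples: int = 6,
                     use_factors: bool = False, factors: pd.Series | None = None) -> set:
    """Genes detected: strictly more than ``cpm_threshold`` CPM in at least
    ``min_samples`` samples.

    The filter is applied to one station's matrix at a time; callers analysing
    several stations run it once per station. By default CPM here uses raw
    library sizes (no normalization factors).
    """
    df = _count_df(counts)
    if min_samples > df.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {df.shape[1]} samples present"
        )
    expr = cpm(df, use_factors=use_factors, factors=factors).values
    n_above = (expr.to_numpy() > cpm_threshold).sum(axis=1)
    return set(df.index[n_above >= min_samples])


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05,
                reference: str | None = None) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th count percentile (as a
    fraction of library size) is closest to the mean of those percentiles.
    Per-gene log2 ratios (M) against the reference are doubly trimmed —
    ``trim_m`` of the M distribution and ``trim_a`` of the average log
    abundance (A) distribution from each tail — and averaged with
    binomial-variance precision weights. Factors are rescaled so their
    geometric mean is 1. Genes with a zero count in either column are
    excluded from that comparison.
    """
    df = _count_df(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    y = df.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    p = y / lib  # proportions
    if reference is None:
        q75 = np.percentile(p, 75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = list(df.columns).index(reference)
    pr, nr = p[:, ref_idx], lib[ref_idx]
    yr = y[:, ref_idx]
    log_factors = np.zeros(df.shape[1])
    for k in range(df.shape[1]):
        if k == ref_idx:
            continue
        ok = (y[:, k] > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"no genes shared with reference for sample {df.columns[k]}")
        m = np.log2(p[ok, k] / pr[ok])
        a = 0.5 * np.log2(p[ok, k] * pr[ok])
        # asymptotic binomial variance of M
        w = (lib[k] - y[ok, k]) / (lib[k] * y[ok, k]) + (nr - yr[ok]) / (nr * yr[ok])
        keep = _double_trim(m, a, trim_m, trim_a)
        if not keep.any():  # fully trimmed (e.g. identical columns): M ~ 0
            log_factors[k] = 0.0
            continue
        log_factors[k] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_factors -= log_factors.mean()  # geometric mean of 2**lf is 1
    return pd.Series(2.0 ** log_factors, index=df.columns, name="tmm_factor")


def _double_trim(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Keep genes whose M and A ranks both fall inside the trim bounds."""
    n = len(m)
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1.0
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1.0
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    return (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)


def fpkm(counts, lengths: pd.Series, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Fragments per kilobase of gene per million mapped fragments.

    value = count / (length/1e3) / (effective library size/1e6), where the
    effective library size is library size x TMM factor when factors are
    supplied.
    """
    df = _count_df(counts)
    missing = df.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes missing from length table: {missing[:10].tolist()}")
    lens = lengths.reindex(df.index).to_numpy(dtype=float)
    lib = df.sum(axis=0).astype(float)
    eff = lib * (factors.reindex(df.columns).to_numpy(dtype=float) if factors is not None else 1.0)
    vals = df.to_numpy(dtype=float) / (lens[:, None] / 1e3) / (eff.to_numpy() / 1e6)
    return ExpressionMatrix(pd.DataFrame(vals, index=df.index, columns=df.columns), "FPKM")


def venn_partition(genes_a: Iterable, genes_b: Iterable) -> tuple[set, set, set]:
    """Partition two detected-gene sets into (shared, only_a, only_b)."""
    sa, sb = set(genes_a), set(genes_b)
    return sa & sb, sa - sb, sb - sa
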