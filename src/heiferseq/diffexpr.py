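"""Two-engine negative-binomial differential expression with permutation eFDR.

Two independent NB tests are run per gene — an exact conditional test on
depth-equalized pseudo-counts (engine 1) and a Wald test from a two-group
NB log-link model (engine 2) — and a gene is called differentially
expressed only when both nominal p-values fall at or below alpha (0.01 by
default). The empirical false discovery rate of that consensus rule is
estimated by permuting sample labels within the station and recording how
many genes the same rule discovers on relabeled data.

Fold changes are oriented as log2(second group / first group), with the
AI-pregnant group first by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm as norm_dist, t as t_dist

from .containers import CountMatrix
from .normalize import tmm_factors

_LN2 = np.log(2.0)
_PHI_POISSON = 1e-10  # below this, use the Poisson/binomial limit


# ---------------------------------------------------------------------------
# label handling


def _count_df(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def _group_masks(labels, group_order=None):
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if group_order is None:
        # AI-pregnant animals are the reference (first) group when present
        if "AI_PREGNANT" in uniq:
            group_order = ("AI_PREGNANT", [u for u in uniq if u != "AI_PREGNANT"][0])
        else:
            group_order = tuple(uniq)
    g1, g2 = group_order
    m1 = labels == g1
    m2 = labels == g2
    if not m1.any() or not m2.any():
        raise ValueError(f"group_order {group_order} not found in labels")
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return m1, m2, (g1, g2)


# ---------------------------------------------------------------------------
# size factors and dispersion estimation


def median_of_ratios_size_factors(counts) -> pd.Series:
    """DESeq-style size factors: median of per-gene ratios to the geometric
    mean reference, computed over genes with no zero count."""
    df = _count_df(counts)
    y = df.to_numpy(dtype=float)
    pos = (y > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene with positive counts in every sample")
    logs = np.log(y[pos])
    ref = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def _moment_dispersions(y: np.ndarray, masks, sf: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion pooled across the two groups.

    Uses Var(y/s) = mu * mean(1/s) + phi * mu^2 within each group.
    """
    z = y / sf
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for m in masks:
        n = int(m.sum())
        zc = z[:, m]
        mu = zc.mean(axis=1)
        v = zc.var(axis=1, ddof=1)
        a = np.mean(1.0 / sf[m])
        w = n - 1
        num += w * (v - mu * a)
        den += w * np.maximum(mu, 1e-300) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = num / den
    phi[~np.isfinite(phi)] = 0.0  # genes with zero mean carry no information
    return np.clip(phi, 0.0, None)


def _nb_loglik_and_cr(y, sf, masks, phi):
    """Profile log-likelihood at dispersion phi with plug-in group means,
    with the Cox-Reid adjustment for the fitted mean parameters."""
    ll = 0.0
    r = 1.0 / max(phi, 1e-12)
    for m in masks:
        yc = y[:, m]
        sc = sf[m]
        lam = yc.sum(axis=1) / sc.sum()
        mu = lam[:, None] * sc[None, :]
        mu = np.maximum(mu, 1e-12)
        ll += np.sum(
            gammaln(yc + r) - gammaln(r) - gammaln(yc + 1.0)
            + r * np.log(r / (r + mu))
            + yc * np.log(mu / (r + mu))
        )
        info = (mu / (1.0 + phi * mu)).sum(axis=1)
        ll -= 0.5 * np.sum(np.log(np.maximum(info, 1e-12)))
    return ll


def estimate_dispersions(
    counts,
    labels=None,
    method: str = "tagwise_shrink",
    size_factors: pd.Series | None = None,
    prior_df: float = 10.0,
    group_order=None,
) -> pd.Series:
    """Per-gene NB dispersion estimates.

    methods: ``moments`` (per-gene pooled moment estimator), ``cml_common``
    (one common value maximizing the Cox-Reid adjusted profile likelihood),
    ``tagwise_shrink`` (moment estimates shrunk toward the common value
    with a prior weight of ``prior_df`` degrees of freedom).

    With ``labels=None`` the estimate is label-free (one pooled group):
    between-group signal then inflates the dispersion of truly DE genes,
    which is the conservative choice required for exchangeable
    permutation inference (see :func:`efdr`).
    """
    df = _count_df(counts)
    y = df.to_numpy(dtype=float)
    if labels is None:
        masks = (np.ones(y.shape[1], dtype=bool),)
        resid_df = y.shape[1] - 1
    else:
        m1, m2, _ = _group_masks(labels, group_order)
        masks = (m1, m2)
        resid_df = y.shape[1] - 2
    sf = (
        size_factors.reindex(df.columns).to_numpy(dtype=float)
        if size_factors is not None
        else df.sum(axis=0).to_numpy(dtype=float) / df.sum(axis=0).mean()
    )
    if method == "moments":
        phi = _moment_dispersions(y, masks, sf)
    elif method in ("cml_common", "tagwise_shrink"):
        res = minimize_scalar(
            lambda lp: -_nb_loglik_and_cr(y, sf, masks, 10.0 ** lp),
            bounds=(-6.0, 1.0),
            method="bounded",
            options={"xatol": 1e-3},
        )
        common = float(10.0 ** res.x)
        if method == "cml_common":
            phi = np.full(y.shape[0], common)
        else:
            tag = _moment_dispersions(y, masks, sf)
            phi = (prior_df * common + resid_df * tag) / (prior_df + resid_df)
    else:
        raise ValueError(f"unknown dispersion method {method!r}")
    return pd.Series(phi, index=df.index, name="dispersion")


# ---------------------------------------------------------------------------
# engine 1: exact conditional NB test


def _exact_pvalue_tables(t_tot: np.ndarray, n1: int, n2: int, phi: np.ndarray):
    """Two-sided exact-test lookup tables.

    For each gene with conditional total t, the group-1 sum S1 given
    S1 + S2 = t follows the NB-convolution conditional law with weights
    a1 = n1/phi, a2 = n2/phi (the binomial(t, n1/(n1+n2)) in the Poisson
    limit). Returns a flat array ``ptab`` and per-gene ``offsets`` so that
    the two-sided minimum-likelihood p-value of s is ptab[offsets[g] + s]:
    the total probability of outcomes no more likely than s, ties included.
    """
    t_tot = np.asarray(t_tot, dtype=np.int64)
    G = len(t_tot)
    sizes = t_tot + 1
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    total = int(sizes.sum())
    gidx = np.repeat(np.arange(G), sizes)
    x = np.arange(total) - np.repeat(offsets, sizes)
    tg = t_tot[gidx]
    phig = np.asarray(phi, dtype=float)[gidx]

    logpmf = np.empty(total)
    pois = phig <= _PHI_POISSON
    if pois.any():
        p1 = n1 / (n1 + n2)
        xs, ts = x[pois], tg[pois]
        logpmf[pois] = (
            gammaln(ts + 1.0) - gammaln(xs + 1.0) - gammaln(ts - xs + 1.0)
            + xs * np.log(p1) + (ts - xs) * np.log(1.0 - p1)
        )
    nb = ~pois
    if nb.any():
        a1 = n1 / phig[nb]
        a2 = n2 / phig[nb]
        xs, ts = x[nb], tg[nb]
        logpmf[nb] = (
            gammaln(xs + a1) - gammaln(xs + 1.0) - gammaln(a1)
            + gammaln(ts - xs + a2) - gammaln(ts - xs + 1.0) - gammaln(a2)
            - (gammaln(ts + a1 + a2) - gammaln(ts + 1.0) - gammaln(a1 + a2))
        )

    ptab = np.empty(total)
    for g in range(G):
        seg = logpmf[offsets[g] : offsets[g] + sizes[g]]
        order = np.argsort(seg, kind="stable")
        sorted_lp = seg[order]
        csum = np.cumsum(np.exp(sorted_lp))
        # include outcomes tying the observed probability; the tolerance
        # absorbs float noise in gammaln (mirror outcomes of a symmetric
        # law are mathematically equal but differ in the last bits)
        last_tie = np.searchsorted(sorted_lp, sorted_lp + 1e-9, side="right") - 1
        p_sorted = csum[last_tie]
        pseg = np.empty(sizes[g])
        pseg[order] = p_sorted
        ptab[offsets[g] : offsets[g] + sizes[g]] = np.minimum(pseg, 1.0)
    return ptab, offsets


def _pseudo_counts(df: pd.DataFrame, factors: pd.Series | None):
    """Counts rescaled to a common effective library size (geometric mean)."""
    lib = df.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    f = (
        factors.reindex(df.columns).to_numpy(dtype=float)
        if factors is not None
        else np.ones(df.shape[1])
    )
    eff = lib * f
    common = np.exp(np.mean(np.log(eff)))
    return df.to_numpy(dtype=float) * (common / eff)[None, :]


def exact_nb_test(
    counts,
    labels,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    group_order=None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Exact conditional NB test per gene (two-sided, minimum-likelihood rule).

    Counts are first adjusted to a common effective library size; the test
    conditions on each gene's pseudo-total and sums the probabilities of
    group-1 sums no more likely than the observed one. log2 fold changes
    come from pseudo-count group means with a small prior count so that
    zero-count groups stay finite.
    """
    df = _count_df(counts)
    m1, m2, order = _group_masks(labels, group_order)
    if factors is None:
        factors = tmm_factors(df)
    if dispersions is None:
        dispersions = estimate_dispersions(df, labels, group_order=order)
    phi = dispersions.reindex(df.index).to_numpy(dtype=float)
    pseudo = _pseudo_counts(df, factors)
    n1, n2 = int(m1.sum()), int(m2.sum())
    t_tot = np.rint(pseudo.sum(axis=1)).astype(np.int64)
    s1 = np.clip(np.rint(pseudo[:, m1].sum(axis=1)).astype(np.int64), 0, t_tot)
    s2 = t_tot - s1
    ptab, offsets = _exact_pvalue_tables(t_tot, n1, n2, phi)
    p = ptab[offsets + s1]
    mean1 = s1 / n1 + prior_count
    mean2 = s2 / n2 + prior_count
    log2fc = np.log2(mean2 / mean1)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=df.index)


# ---------------------------------------------------------------------------
# engine 2: Wald test from the two-group NB log-link model


def _newton_group_mean(y, sf, phi, w, tol=1e-8, max_iter=100):
    """Fit log group means of the NB model by Newton scoring.

    y: (G, S) counts; sf: (S,) size factors; phi: (G,) dispersions;
    w: (S,) or (S, P) 0/1 group membership. Returns (eta, info, converged)
    with shapes (G,) or (G, P).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    squeeze = w.ndim == 1
    if squeeze:
        w = w[:, None]
    G, S = y.shape
    P = w.shape[1]
    tot_y = y @ w                      # (G, P)
    tot_s = sf @ w                     # (P,)
    zero = tot_y <= 0
    eta = np.log(np.maximum(tot_y, 0.5) / tot_s[None, :])
    phi3 = phi[:, None, None]
    sf3 = sf[None, :, None]
    w3 = w[None, :, :]
    y3 = y[:, :, None]
    converged = np.zeros((G, P), dtype=bool)
    for _ in range(max_iter):
        mu = sf3 * np.exp(eta[:, None, :])
        denom = 1.0 + phi3 * mu
        U = ((y3 - mu) / denom * w3).sum(axis=1)
        info = (mu / denom * w3).sum(axis=1)
        step = np.where(info > 0, U / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        converged = np.abs(step) < tol
        if converged.all():
            break
    mu = sf3 * np.exp(eta[:, None, :])
    info = (mu / (1.0 + phi3 * mu) * w3).sum(axis=1)
    converged = converged & ~zero
    if squeeze:
        return eta[:, 0], info[:, 0], converged[:, 0], zero[:, 0]
    return eta, info, converged, zero


def wald_nb_test(
    counts,
    labels,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    group_order=None,
    prior_count: float = 0.125,
    p_reference: str = "normal",
) -> pd.DataFrame:
    """Wald test on the group coefficient of a two-group NB log-link model.

    The model y_gj ~ NB(s_j * lambda_{g,group(j)}, phi_g) is fit by Newton
    scoring (equivalent to IRLS for this saturated two-group design). The
    Wald statistic beta/SE uses the observed Fisher information; by default
    it is referred to a t distribution with n_samples - 2 degrees of
    freedom (``p_reference='normal'`` for the large-sample reference).
    Genes that fail to converge get p = NaN and are excluded downstream.
    """
    df = _count_df(counts)
    m1, m2, order = _group_masks(labels, group_order)
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(df)
    if dispersions is None:
        dispersions = estimate_dispersions(
            df, labels, size_factors=size_factors, group_order=order
        )
    y = df.to_numpy(dtype=float)
    sf = size_factors.reindex(df.columns).to_numpy(dtype=float)
    phi = dispersions.reindex(df.index).to_numpy(dtype=float)
    eta1, i1, c1, z1 = _newton_group_mean(y, sf, phi, m1.astype(float))
    eta2, i2, c2, z2 = _newton_group_mean(y, sf, phi, m2.astype(float))
    beta = eta2 - eta1
    se = np.sqrt(1.0 / np.maximum(i1, 1e-300) + 1.0 / np.maximum(i2, 1e-300))
    stat = beta / se
    n = y.shape[1]
    if p_reference == "t":
        p = 2.0 * t_dist.sf(np.abs(stat), df=n - 2)
    elif p_reference == "normal":
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(stat))
    else:
        raise ValueError("p_reference must be 't' or 'normal'")
    ok = c1 & c2
    p = np.where(ok, p, np.nan)
    # report a finite log2 fold change even when a group is all-zero
    lam1 = np.where(z1, 0.0, np.exp(eta1))
    lam2 = np.where(z2, 0.0, np.exp(eta2))
    log2fc = np.where(
        z1 | z2,
        np.log2((lam2 + prior_count) / (lam1 + prior_count)),
        beta / _LN2,
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "converged": ok}, index=df.index
    )


# ---------------------------------------------------------------------------
# consensus rule and empirical FDR


def de_table(
    counts,
    labels,
    alpha: float = 0.01,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    group_order=None,
) -> pd.DataFrame:
    """Run both engines and apply the two-engine consensus rule.

    Returns a per-gene table (log2fc from the exact engine, p_exact,
    p_wald, log2fc_wald, consensus_deg); ``alpha`` is recorded in
    ``result.attrs['alpha']``.
    """
    df = _count_df(counts)
    m1, m2, order = _group_masks(labels, group_order)
    if factors is None:
        factors = tmm_factors(df)
    if dispersions is None:
        dispersions = estimate_dispersions(df, labels, group_order=order)
    ex = exact_nb_test(df, labels, factors, dispersions, group_order=order)
    wa = wald_nb_test(df, labels, dispersions=dispersions, group_order=order)
    res = pd.DataFrame(
        {
            "log2fc": ex["log2fc"],
            "log2fc_wald": wa["log2fc"],
            "p_exact": ex["p"],
            "p_wald": wa["p"],
        },
        index=df.index,
    )
    res["consensus_deg"] = (res["p_exact"] <= alpha) & (res["p_wald"] <= alpha)
    res.attrs["alpha"] = alpha
    res.attrs["group_order"] = order
    return res


def consensus_deg(result: pd.DataFrame, alpha: float = 0.01) -> set:
    """Genes called by both engines at nominal p <= alpha (NaN never passes)."""
    keep = (result["p_exact"] <= alpha) & (result["p_wald"] <= alpha)
    return set(result.index[keep.fillna(False)])


@dataclass
class EFDREstimate:
    """Empirical FDR of the discovery rule at a nominal p threshold."""

    alpha: float
    n_observed: int
    mean_null_discoveries: float
    efdr: float | None
    undefined: bool
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not self.undefined and self.efdr is not None:
            assert 0.0 <= self.efdr <= 1.0


def efdr(
    counts,
    labels,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    group_order=None,
    engine: str = "consensus",
) -> EFDREstimate:
    """Label-permutation empirical FDR of the DE discovery rule.

    Sample labels are permuted uniformly (group sizes preserved) and both
    test engines are recomputed per permutation. Nuisance quantities —
    TMM factors, size factors and dispersions — are estimated once,
    *without using the labels* (pooled one-group dispersions), so the
    observed labeling is exchangeable with the permuted ones and the eFDR
    is calibrated (~1 on pure-null data). eFDR = min(1, mean null
    discoveries / observed discoveries); undefined when the observed set
    is empty. ``engine`` selects the discovery rule: 'consensus'
    (default), 'exact' or 'wald'. Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if engine not in ("consensus", "exact", "wald"):
        raise ValueError(f"unknown engine {engine!r}")
    df = _count_df(counts)
    m1, m2, order = _group_masks(labels, group_order)
    n1, n2 = int(m1.sum()), int(m2.sum())
    S = n1 + n2
    if comb(S, n1) < n_perm:
        warnings.warn(
            f"only {comb(S, n1)} distinct label assignments exist for group sizes "
            f"({n1}, {n2}); permutations are sampled with replacement",
            stacklevel=2,
        )
    factors = tmm_factors(df)
    dispersions = estimate_dispersions(df, labels=None)  # label-free
    phi = dispersions.to_numpy(dtype=float)
    y = df.to_numpy(dtype=float)
    sf = median_of_ratios_size_factors(df).to_numpy(dtype=float)

    # exact engine: conditional p-value lookup tables are label-free
    pseudo = _pseudo_counts(df, factors)
    t_tot = np.rint(pseudo.sum(axis=1)).astype(np.int64)
    ptab, offsets = _exact_pvalue_tables(t_tot, n1, n2, phi)

    def wald_hits(mask1_col: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """Wald-engine calls for one labeling, restricted to gene ``rows``."""
        ysub, psub = y[rows], phi[rows]
        eta1, i1, c1, _ = _newton_group_mean(ysub, sf, psub, mask1_col)
        eta2, i2, c2, _ = _newton_group_mean(ysub, sf, psub, 1.0 - mask1_col)
        se = np.sqrt(1.0 / np.maximum(i1, 1e-300) + 1.0 / np.maximum(i2, 1e-300))
        p_wa = 2.0 * norm_dist.sf(np.abs((eta2 - eta1) / se))
        return (p_wa <= alpha) & c1 & c2

    def discoveries(mask1: np.ndarray) -> np.ndarray:
        """Per-permutation discovery counts for mask1 of shape (S, P)."""
        P = mask1.shape[1]
        if engine == "wald":
            out = np.empty(P, dtype=np.int64)
            for k in range(P):
                out[k] = int(wald_hits(mask1[:, k], np.arange(len(y))).sum())
            return out
        s1 = np.clip(np.rint(pseudo @ mask1).astype(np.int64), 0, t_tot[:, None])
        ex_hits = ptab[offsets[:, None] + s1] <= alpha
        if engine == "exact":
            return ex_hits.sum(axis=0)
        # consensus is an intersection: the Wald engine only needs to run on
        # the genes the exact engine already called in that permutation
        out = np.empty(P, dtype=np.int64)
        for k in range(P):
            rows = np.flatnonzero(ex_hits[:, k])
            out[k] = int(wald_hits(mask1[:, k], rows).sum()) if len(rows) else 0
        return out

    base = m1.astype(float)
    n_obs = int(discoveries(base[:, None])[0])

    rng = np.random.default_rng(seed)
    chunk = 256
    null_counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        masks = np.empty((S, p))
        for k in range(p):
            masks[:, k] = rng.permutation(base)
        null_counts[done : done + p] = discoveries(masks)
        done += p

    mean_null = float(null_counts.mean())
    if n_obs == 0:
        return EFDREstimate(alpha, 0, mean_null, None, True, n_perm, seed)
    return EFDREstimate(
        alpha, n_obs, mean_null, min(1.0, mean_null / n_obs), False, n_perm, seed
    )
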