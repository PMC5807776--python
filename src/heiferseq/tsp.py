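"""Exhaustive top-scoring-pair (TSP) scan and rank-based classification.

For every pair of genes (i, j) the primary score is
delta = |P(Xi < Xj | class 1) - P(Xi < Xj | class 2)|, estimated from the
within-sample ordering of expression (FPKM) with strict inequalities —
tied values contribute to neither frequency. The secondary score gamma is
the absolute difference between classes of the mean within-sample rank
difference of the two genes, used to break delta ties. Pairs are ranked by
(delta desc, gamma desc, lexicographic ids); the accounting counts ordered
pairs, n(n-1), while reports keep one orientation per pair (the one whose
"Xi below Xj" pattern indicates class 1).

The scan streams gene blocks so memory stays bounded and results are
independent of the block size. Significance of the maximum score is
assessed by permuting class labels (group sizes preserved) and recording
the permutation distribution of the maximum delta over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix


def pair_count(n_genes: int) -> int:
    """Number of ordered gene pairs evaluated by the exhaustive scan."""
    return n_genes * (n_genes - 1)


@dataclass
class TSPPair:
    """One oriented gene pair: Xi < Xj (within a sample) indicates class 1."""

    gene_i: str
    gene_j: str
    delta: float
    gamma: float
    f1: float  # P(Xi < Xj | class 1)
    f2: float  # P(Xi < Xj | class 2)

    def key(self):
        return (-self.delta, -self.gamma, self.gene_i, self.gene_j)


@dataclass
class TSPScanResult:
    pairs: list[TSPPair]
    n_pairs_evaluated: int
    max_delta: float
    n_pairs_at_max: int  # unordered pairs achieving the maximum delta
    n_genes: int
    classes: tuple[str, str]
    class_sizes: tuple[int, int]
    sample_ids: list[str]
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_i": p.gene_i,
                    "gene_j": p.gene_j,
                    "delta": p.delta,
                    "gamma": p.gamma,
                    "freq_class1": p.f1,
                    "freq_class2": p.f2,
                }
                for p in self.pairs
            ]
        )


def _expr_df(expr) -> pd.DataFrame:
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return df


def _class_masks(labels, positive=None):
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two classes required, got {uniq}")
    if positive is not None:
        if positive not in uniq:
            raise ValueError(f"positive class {positive!r} not in labels")
        uniq = [positive] + [u for u in uniq if u != positive]
    m1 = labels == uniq[0]
    m2 = labels == uniq[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return m1, m2, (uniq[0], uniq[1])


def _pair_stats(x: np.ndarray, i: int, j: int, m1, m2):
    """Exact (f1, f2) for one ordered pair, strict inequality."""
    less = x[i] < x[j]
    return less[m1].mean(), less[m2].mean()


def tsp_scan(
    expr,
    labels,
    top_k: int = 20,
    positive=None,
    block_size: int = 256,
) -> TSPScanResult:
    """Exhaustive TSP scan; returns the ``top_k`` pairs under the total order
    (delta desc, gamma desc, lexicographic gene ids), mirror pairs
    deduplicated with the class-1-indicating orientation kept."""
    df = _expr_df(expr)
    m1, m2, classes = _class_masks(labels, positive)
    x = df.to_numpy(dtype=float)
    G, S = x.shape
    if G < 2:
        raise ValueError("need at least 2 genes")
    gene_ids = np.asarray(df.index.astype(str))
    n1, n2 = int(m1.sum()), int(m2.sum())
    m1f = m1.astype(float)
    m2f = m2.astype(float)
    denom = n1 * n2

    # delta and gamma live on discrete grids (multiples of 1/(n1*n2) and of
    # 1/(2*n1*n2)); ordering uses exact integer/half-integer numerators so
    # that ties are exact and the ranking is a true total order
    ranks = rankdata(x, axis=0)  # average ranks within each sample
    dnum = ranks[:, m1].sum(axis=1) * n2 - ranks[:, m2].sum(axis=1) * n1

    candidates: list[tuple] = []  # (delta_num, gamma_num, i, j, c1, c2) with i < j
    max_num = 0.0
    count_at_max = 0
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        less = x[start:stop, None, :] < x[None, :, :]  # (b, G, S)
        c1 = less @ m1f  # class-1 samples with Xi < Xj: exact small integers
        c2 = less @ m2f
        delta_num = np.abs(c1 * n2 - c2 * n1)
        # keep one representative per unordered pair: global column > row
        rows = np.arange(start, stop)
        upper = np.arange(G)[None, :] > rows[:, None]
        dvals = np.where(upper, delta_num, -1.0)
        bmax = dvals.max()
        if bmax > max_num:
            max_num, count_at_max = bmax, int((dvals == bmax).sum())
        elif bmax == max_num and bmax >= 0:
            count_at_max += int((dvals == bmax).sum())
        gam = np.abs(dnum[rows][:, None] - dnum[None, :])
        flat = dvals.ravel()
        n_valid = int(upper.sum())
        if n_valid == 0:
            continue
        take = min(top_k, n_valid)
        kth = np.partition(flat, flat.size - take)[flat.size - take]
        idx = np.flatnonzero(flat >= kth)
        bi, bj = np.unravel_index(idx, dvals.shape)
        gi = gene_ids[rows[bi]]
        gj = gene_ids[bj]
        order = np.lexsort((gj, gi, -gam[bi, bj], -flat[idx]))[:take]
        for k in order:
            r, c = int(bi[k]), int(bj[k])
            candidates.append(
                (dvals[r, c], gam[r, c], rows[r], c, c1[r, c], c2[r, c])
            )

    candidates.sort(
        key=lambda t: (-t[0], -t[1], gene_ids[t[2]], gene_ids[t[3]])
    )
    pairs = []
    for delta_num, gamma_num, i, j, c1v, c2v in candidates[:top_k]:
        f1v, f2v = c1v / n1, c2v / n2
        if f2v > f1v:
            # keep the orientation whose Xi<Xj pattern indicates class 1
            f1v, f2v = _pair_stats(x, j, i, m1, m2)
            i, j = j, i
        pairs.append(
            TSPPair(
                gene_ids[i],
                gene_ids[j],
                float(delta_num / denom),
                float(gamma_num / denom),
                float(f1v),
                float(f2v),
            )
        )
    max_delta = float(max_num / denom)
    return TSPScanResult(
        pairs=pairs,
        n_pairs_evaluated=pair_count(G),
        max_delta=float(max_delta),
        n_pairs_at_max=count_at_max,
        n_genes=G,
        classes=classes,
        class_sizes=(int(m1.sum()), int(m2.sum())),
        sample_ids=list(df.columns.astype(str)),
    )


def _max_delta(x: np.ndarray, w1: np.ndarray, w2: np.ndarray, block_size: int) -> float:
    best = 0.0
    G = x.shape[0]
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        less = x[start:stop, None, :] < x[None, :, :]
        best = max(best, float(np.abs(less @ w1 - less @ w2).max()))
    return best


def tsp_permutation_p(
    expr,
    labels,
    n_perm: int = 5000,
    seed: int = 0,
    positive=None,
    block_size: int | None = None,
) -> float:
    """Permutation p-value of the maximum pair score.

    For each label permutation (class sizes preserved) the maximum delta
    over all pairs is recorded; p = (1 + #{null max >= observed max}) /
    (1 + n_perm), so the smallest attainable value is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = _expr_df(expr)
    m1, m2, _ = _class_masks(labels, positive)
    x = df.to_numpy(dtype=float)
    G, S = x.shape
    n1, n2 = int(m1.sum()), int(m2.sum())
    if block_size is None:
        block_size = max(1, min(G, int(2e5) // max(G, 1)))
    obs = _max_delta(x, m1 / n1, m2 / n2, block_size)

    rng = np.random.default_rng(seed)
    base = m1.astype(float)
    masks = np.empty((S, n_perm))
    for k in range(n_perm):
        masks[:, k] = rng.permutation(base)
    w1 = masks / n1
    w2 = (1.0 - masks) / n2

    null_max = np.zeros(n_perm)
    perm_chunk = max(1, int(2e7) // max(block_size * G, 1))
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        less = (x[start:stop, None, :] < x[None, :, :]).reshape(-1, S).astype(np.float64)
        for p0 in range(0, n_perm, perm_chunk):
            p1 = min(p0 + perm_chunk, n_perm)
            diff = np.abs(less @ w1[:, p0:p1] - less @ w2[:, p0:p1])
            np.maximum(null_max[p0:p1], diff.max(axis=0), out=null_max[p0:p1])
    exceed = int((null_max >= obs - 1e-9).sum())
    return (1 + exceed) / (1 + n_perm)


def tsp_classify(
    expr,
    pairs: list[TSPPair],
    true_labels=None,
    classes: tuple[str, str] | None = None,
    class_sizes: tuple[int, int] | None = None,
):
    """Majority-vote classification from a list of oriented pairs.

    Per pair a sample votes class 1 iff Xi < Xj (ties abstain); the
    majority over pairs decides, with vote ties resolved toward the larger
    class (class 1 when class sizes tie or are unknown). Returns
    (predicted labels, per-class accuracy or None, overall score or None)
    where the overall score is the top pair's delta on the given labels.
    """
    df = _expr_df(expr)
    if classes is None:
        classes = ("class1", "class2")
    for p in pairs:
        for gid in (p.gene_i, p.gene_j):
            if gid not in df.index:
                raise KeyError(f"gene {gid} not present in expression matrix")
    x = df.to_numpy(dtype=float)
    loc = {g: k for k, g in enumerate(df.index.astype(str))}
    net = np.zeros(x.shape[1])
    for p in pairs:
        xi, xj = x[loc[p.gene_i]], x[loc[p.gene_j]]
        net += np.where(xi < xj, 1.0, 0.0) - np.where(xi > xj, 1.0, 0.0)

    if true_labels is not None and class_sizes is None:
        tl = np.asarray(true_labels)
        class_sizes = (int((tl == classes[0]).sum()), int((tl == classes[1]).sum()))
    larger = classes[0]
    if class_sizes is not None and class_sizes[1] > class_sizes[0]:
        larger = classes[1]
    predicted = np.where(net > 0, classes[0], np.where(net < 0, classes[1], larger))

    accuracy = None
    overall = None
    if true_labels is not None:
        tl = np.asarray(true_labels)
        accuracy = {
            c: float((predicted[tl == c] == c).mean()) for c in classes if (tl == c).any()
        }
        m1, m2, _ = _class_masks(tl, positive=classes[0])
        top = pairs[0]
        f1, f2 = _pair_stats(x, loc[top.gene_i], loc[top.gene_j], m1, m2)
        overall = float(abs(f1 - f2))
    return predicted, accuracy, overall


def ratio_features(expr, pairs: list[TSPPair], epsilon: float = 1.0) -> pd.DataFrame:
    """log2((Xi + eps)/(Xj + eps)) per sample, one row per oriented pair."""
    if len(pairs) < 1:
        raise ValueError("at least one pair required")
    df = _expr_df(expr)
    rows = {}
    for p in pairs:
        xi = df.loc[p.gene_i].to_numpy(dtype=float)
        xj = df.loc[p.gene_j].to_numpy(dtype=float)
        rows[f"{p.gene_i}/{p.gene_j}"] = np.log2((xi + epsilon) / (xj + epsilon))
    return pd.DataFrame(rows, index=df.columns).T
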