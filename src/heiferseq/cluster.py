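"""Hierarchical clustering of pair-ratio features with bootstrap support
and hypergeometric enrichment of cluster composition.

Samples are clustered from the log-ratio features of the top scoring gene
pairs (rows = pairs, columns = samples). Cluster robustness is the plain
bootstrap proportion (BP): features (pairs) are resampled with replacement,
the tree is rebuilt, and each internal node's support is the fraction of
bootstrap trees containing the same leaf set as a cluster. Whether a
cluster is enriched for one pregnancy outcome is tested with the exact
upper-tail hypergeometric probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

_DISTANCES = ("correlation", "euclidean")
_LINKAGES = ("average", "complete")


@dataclass
class Dendrogram:
    """Merge tree over samples with optional per-node bootstrap support."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    distance: str
    linkage: str
    bootstrap_proportion: dict[frozenset, float] | None = None
    n_bootstrap: int | None = None
    seed: int | None = None

    def clusters(self) -> list[frozenset]:
        """Leaf sets of all internal nodes, root included."""
        tree = to_tree(self.linkage_matrix)
        out: list[frozenset] = []

        def walk(node):
            if node.is_leaf():
                return frozenset([self.sample_ids[node.id]])
            left = walk(node.get_left())
            right = walk(node.get_right())
            merged = left | right
            out.append(merged)
            return merged

        walk(tree)
        return out

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic_matrix(self) -> pd.DataFrame:
        from scipy.cluster.hierarchy import cophenet

        coph = cophenet(self.linkage_matrix)
        n = len(self.sample_ids)
        mat = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        mat[iu] = coph
        mat += mat.T
        return pd.DataFrame(mat, index=self.sample_ids, columns=self.sample_ids)

    def to_newick(self, with_support: bool = True) -> str:
        """Newick string; internal-node labels are BP values when present."""
        tree = to_tree(self.linkage_matrix)
        bp = self.bootstrap_proportion or {}

        def leafset(node):
            return frozenset(self.sample_ids[i] for i in node.pre_order(lambda n: n.id))

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            inner = ",".join(
                render(c, node.dist) for c in (node.get_left(), node.get_right())
            )
            label = ""
            if with_support:
                support = bp.get(leafset(node))
                if support is not None:
                    label = f"{support:.4g}"
            return f"({inner}){label}:{length:.6g}"

        left, right = tree.get_left(), tree.get_right()
        inner = ",".join(render(c, tree.dist) for c in (left, right))
        label = ""
        if with_support and bp:
            label = f"{bp.get(leafset(tree), 1.0):.4g}"
        return f"({inner}){label};"


def _sample_distances(features: np.ndarray, distance: str, strict: bool = True) -> np.ndarray:
    """Condensed distance matrix between samples (columns of ``features``)."""
    x = features.T  # samples x features
    if distance == "euclidean":
        return pdist(x, "euclidean")
    if distance == "correlation":
        sd = x.std(axis=1)
        if (sd == 0).any():
            if strict:
                raise ValueError(
                    "correlation distance undefined for constant sample columns"
                )
            # bootstrap replicate degenerated: treat as uncorrelated
            x = x.copy()
            x[sd == 0] += np.random.default_rng(0).normal(0, 1e-9, x.shape[1])
        d = pdist(x, "correlation")
        return np.nan_to_num(d, nan=1.0)
    raise ValueError(f"distance must be one of {_DISTANCES}")


def hcluster(
    features,
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Hierarchical clustering of samples from a (pairs x samples) feature table."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")
    if not np.isfinite(arr).all():
        raise ValueError("features contain non-finite values")
    z = scipy_linkage(_sample_distances(arr, distance), method=linkage)
    return Dendrogram(z, list(df.columns.astype(str)), distance, linkage)


def bootstrap_support(
    features,
    distance: str = "correlation",
    linkage: str = "average",
    n_boot: int = 5000,
    seed: int = 0,
) -> Dendrogram:
    """Dendrogram with bootstrap proportions.

    Feature rows (gene pairs) are resampled with replacement ``n_boot``
    times; BP(node) = fraction of bootstrap trees containing the node's
    leaf set as a cluster. Deterministic under ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    dend = hcluster(df, distance, linkage)
    targets = dend.clusters()
    hits = {c: 0 for c in targets}
    arr = df.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    k = arr.shape[0]
    ids = list(df.columns.astype(str))
    for _ in range(n_boot):
        rows = rng.integers(0, k, size=k)
        try:
            d = _sample_distances(arr[rows], distance, strict=False)
            z = scipy_linkage(d, method=linkage)
        except ValueError:
            continue
        boot = Dendrogram(z, ids, distance, linkage)
        present = set(boot.clusters())
        for c in targets:
            if c in present:
                hits[c] += 1
    dend.bootstrap_proportion = {c: hits[c] / n_boot for c in targets}
    dend.n_bootstrap = n_boot
    dend.seed = seed
    return dend


def main_split_clusters(dend: Dendrogram) -> list[frozenset]:
    """The two sample sets produced by the final (root) merge."""
    tree = to_tree(dend.linkage_matrix)
    out = []
    for child in (tree.get_left(), tree.get_right()):
        out.append(
            frozenset(dend.sample_ids[i] for i in child.pre_order(lambda n: n.id))
        )
    return out


def cluster_enrichment(cluster_members, positives, n_total: int) -> float:
    """Exact upper-tail hypergeometric enrichment p-value.

    p = P(X >= k) with X ~ Hypergeom(N=n_total, K=|positives|, n=|cluster|)
    and k = |cluster & positives|.
    """
    cluster = set(cluster_members)
    pos = set(positives)
    if len(cluster) > n_total or len(pos) > n_total:
        raise ValueError("set sizes exceed the total number of samples")
    k = len(cluster & pos)
    return float(hypergeom.sf(k - 1, n_total, len(pos), len(cluster)))
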