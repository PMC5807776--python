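"""Synthetic RNA-seq count and qPCR generators with planted ground truth.

The generator emulates the statistical structure of a two-group bulk
RNA-seq contrast from peripheral white blood cells: negative-binomial
fragment counts with lognormal baseline expression, gamma-distributed
gene-wise overdispersion, optional planted differentially expressed genes
at stated log2 fold changes, and optional planted "reversal" gene pairs
whose within-sample expression ordering flips between groups. The same
planted truth can drive a matching qPCR cycle-threshold table.

The default configuration is a desk-scale preset (2,000 genes, library
sizes 2-4 x 10^5 fragments) that preserves the study design shape (two
outcome groups of ~6 animals at one station) while letting the full
pipeline, including permutation-based error control, run in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd

from .containers import CountMatrix, OUTCOMES


@dataclass
class SimConfig:
    """Parameters of one simulated two-group count matrix.

    dispersion=None draws gene-wise NB dispersions phi from a
    Gamma(shape=2, mean=0.1) distribution (variance = m + phi m^2); a float
    fixes phi for every gene, and 0.0 gives Poisson counts.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int] = (6, 6)
    mean_log_expression: float = 2.0
    mean_log_sd: float = 1.5
    dispersion: float | None = None
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.1
    library_size_range: tuple[int, int] = (200_000, 400_000)
    n_de_genes: int = 0
    de_log2fc_range: tuple[float, float] = (1.0, 2.0)
    n_reversal_pairs: int = 0
    reversal_gap_range: tuple[float, float] = (1.3, 2.0)
    seed: int = 0
    station: str = "A"
    group_labels: tuple[str, str] = ("AI_PREGNANT", "NB_PREGNANT")

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mean_log_sd <= 0:
            raise ValueError("mean_log_sd must be positive")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library_size_range")
        if self.n_de_genes < 0 or self.n_reversal_pairs < 0:
            raise ValueError("planting counts must be non-negative")
        if self.n_de_genes + 2 * self.n_reversal_pairs > self.n_genes:
            raise ValueError(
                f"cannot plant {self.n_de_genes} DE genes and "
                f"{self.n_reversal_pairs} reversal pairs in {self.n_genes} genes"
            )
        for lab in self.group_labels:
            if lab not in OUTCOMES:
                raise ValueError(f"group label {lab!r} not one of {OUTCOMES}")


@dataclass
class SimTruth:
    """Planted ground truth of one simulation.

    de_genes maps gene id -> true log2 fold change (group 2 over group 1);
    reversal_pairs lists (gene_i, gene_j) pairs, oriented so that gene_i's
    mean is below gene_j's in group 1 and above it in group 2; the pairs
    are disjoint from each other and from the DE genes.
    """

    de_genes: dict[str, float]
    reversal_pairs: list[tuple[str, str]]
    baseline_means: pd.Series
    dispersions: pd.Series
    group_means: pd.DataFrame = None  # type: ignore[assignment]  # genes x 2 relative means

    def log2fc(self, gene_id: str) -> float:
        """True log2 fold change (group2/group1) for any gene in the matrix."""
        m = self.group_means.loc[gene_id]
        return float(np.log2(m.iloc[1] / m.iloc[0]))


def simulate_counts(config: SimConfig):
    """Draw a (CountMatrix, sample table, gene lengths, SimTruth) quadruple.

    Counts are NB with mean = library size x group-specific expression
    proportion; planted DE genes split their fold change symmetrically
    (x 2^{-fc/2} in group 1, x 2^{+fc/2} in group 2) so overall library
    composition stays stable; reversal pairs swap the two genes' means in
    group 2, with the partner mean set within ``reversal_gap_range`` of the
    anchor so the flip is realistic rather than degenerate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n1, n2 = config.group_sizes
    gene_ids = pd.Index([f"GENE{str(i).zfill(5)}" for i in range(g)], name="gene_id")

    base = np.exp(rng.normal(config.mean_log_expression, config.mean_log_sd, size=g))
    if config.dispersion is None:
        scale = config.dispersion_mean / config.dispersion_shape
        phi = rng.gamma(config.dispersion_shape, scale, size=g)
    else:
        phi = np.full(g, float(config.dispersion))
    lengths_arr = np.maximum(
        100, np.round(np.exp(rng.normal(np.log(1500), 0.5, size=g)))
    ).astype(int)

    # choose disjoint planted gene sets
    order = rng.permutation(g)
    rev_idx = order[: 2 * config.n_reversal_pairs]
    de_idx = order[2 * config.n_reversal_pairs : 2 * config.n_reversal_pairs + config.n_de_genes]

    mean1 = base.copy()
    mean2 = base.copy()
    de_genes: dict[str, float] = {}
    if config.n_de_genes:
        lo, hi = config.de_log2fc_range
        fc = rng.uniform(lo, hi, size=config.n_de_genes)
        fc *= rng.choice([-1.0, 1.0], size=config.n_de_genes)
        mean1[de_idx] = base[de_idx] * 2.0 ** (-fc / 2)
        mean2[de_idx] = base[de_idx] * 2.0 ** (+fc / 2)
        de_genes = {gene_ids[i]: float(f) for i, f in zip(de_idx, fc)}

    # reversal planting works on the length-normalized (FPKM) scale, since
    # the pair analysis orders genes within samples on that scale
    reversal_pairs: list[tuple[str, str]] = []
    bands: list[tuple[float, float]] = []
    for k in range(config.n_reversal_pairs):
        i, j = rev_idx[2 * k], rev_idx[2 * k + 1]
        gap = rng.uniform(*config.reversal_gap_range)
        lo_v = base[i] / lengths_arr[i]
        hi_v = lo_v * gap  # partner forced inside the stated gap band
        mean1[i], mean1[j] = lo_v * lengths_arr[i], hi_v * lengths_arr[j]
        mean2[i], mean2[j] = hi_v * lengths_arr[i], lo_v * lengths_arr[j]
        base[j] = hi_v * lengths_arr[j]
        reversal_pairs.append((gene_ids[i], gene_ids[j]))
        bands.append((lo_v, hi_v))
    if bands:
        # a third gene inside a swapped band would itself form a perfect
        # reversal with either pair member; relocate such genes just outside
        # the band so the planted pair is the unique flip
        margin = 1.1
        pair_genes = set(rev_idx[: 2 * config.n_reversal_pairs].tolist())
        v = base / lengths_arr
        for gi in range(config.n_genes):
            if gi in pair_genes:
                continue
            for lo, hi in bands:
                if lo / margin < v[gi] < hi * margin:
                    shift = (hi * margin) / v[gi] if rng.random() < 0.5 else (lo / margin) / v[gi]
                    base[gi] *= shift
                    mean1[gi] *= shift
                    mean2[gi] *= shift
                    v[gi] *= shift

    group_means = pd.DataFrame(
        {"group1": mean1, "group2": mean2}, index=gene_ids
    )
    prop1 = mean1 / mean1.sum()
    prop2 = mean2 / mean2.sum()

    lo, hi = config.library_size_range
    lib = rng.integers(lo, hi + 1, size=n1 + n2)
    sample_ids = [f"{config.station}{str(i + 1).zfill(2)}" for i in range(n1 + n2)]
    mu = np.empty((g, n1 + n2))
    mu[:, :n1] = prop1[:, None] * lib[:n1]
    mu[:, n1:] = prop2[:, None] * lib[n1:]

    counts = _nb_draw(rng, mu, phi[:, None])
    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "station": config.station,
            "outcome": [config.group_labels[0]] * n1 + [config.group_labels[1]] * n2,
        }
    )
    lengths = pd.Series(lengths_arr, index=gene_ids, name="length")
    truth = SimTruth(
        de_genes=de_genes,
        reversal_pairs=reversal_pairs,
        baseline_means=pd.Series(base, index=gene_ids),
        dispersions=pd.Series(phi, index=gene_ids),
        group_means=group_means,
    )
    return matrix, samples, lengths, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2) draws; phi -> 0 falls back to Poisson."""
    mu, phi = np.broadcast_arrays(mu, phi)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_qpcr(
    truth: SimTruth,
    samples: pd.DataFrame,
    genes: list[str],
    reference_gene: str,
    ct_intercept: float = 25.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR cycle-threshold table consistent with the planted truth.

    CT = intercept - log2(true relative expression of the gene in the
    sample's group) + Gaussian noise. The reference gene must have
    group-independent expression (true log2 fold change 0) so its CT
    distribution is identical across groups.
    """
    rng = np.random.default_rng(seed)
    all_genes = list(dict.fromkeys(list(genes) + [reference_gene]))
    known = set(truth.group_means.index)
    unknown = [gid for gid in all_genes if gid not in known]
    if unknown:
        raise KeyError(f"genes not present in simulation truth: {unknown}")
    if abs(truth.log2fc(reference_gene)) > 1e-12:
        raise ValueError(
            f"reference gene {reference_gene} has group-dependent expression "
            f"(true log2FC {truth.log2fc(reference_gene):.3g})"
        )
    group_of = dict(zip(samples["sample_id"], samples["outcome"]))
    group_order = list(dict.fromkeys(samples["outcome"]))
    if len(group_order) != 2:
        raise ValueError("qPCR simulation expects exactly two outcome groups")
    col = {group_order[0]: "group1", group_order[1]: "group2"}
    records = []
    for sid in samples["sample_id"]:
        grp = col[group_of[sid]]
        for gid in all_genes:
            expr = truth.group_means.loc[gid, grp]
            ct = ct_intercept - np.log2(expr) + rng.normal(0.0, noise_sd)
            records.append((sid, gid, ct))
    return pd.DataFrame(records, columns=["sample_id", "gene_id", "ct"])


def n_distinct_assignments(n1: int, n2: int) -> int:
    """Number of distinct two-group label assignments preserving group sizes."""
    return comb(n1 + n2, n1)
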