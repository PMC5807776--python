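"""Core in-memory containers shared across the pipeline.

The analysis operates on read-pair (fragment) counts for genes across a
handful of blood samples, together with a sample sheet mapping each animal
to its experimental station and pregnancy outcome, and a table of gene
lengths used only for FPKM. All containers are thin, validated wrappers
around pandas objects so they compose with the scientific Python stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three pregnancy outcomes: pregnant to artificial insemination,
#: pregnant to natural breeding later in the season, or not pregnant.
OUTCOMES = ("AI_PREGNANT", "NB_PREGNANT", "NOT_PREGNANT")

#: Summary rows emitted by the htseq-count dialect, in canonical order.
HTSEQ_SPECIAL_ROWS = (
    "__no_feature",
    "__ambiguous",
    "__too_low_aQual",
    "__not_aligned",
    "__alignment_not_unique",
)


@dataclass
class CountMatrix:
    """Integer gene x sample matrix of read-pair counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, genes as rows, samples as columns.
    special : pandas.DataFrame
        Per-sample "__"-prefixed summary counters (may be empty).
    """

    counts: pd.DataFrame
    special: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.special is None:
            self.special = pd.DataFrame(
                index=pd.Index([], dtype=object), columns=self.counts.columns
            )
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        bad = [g for g in counts.index if str(g).startswith("__")]
        if bad:
            raise ValueError(f"'__'-prefixed ids are summary rows, not genes: {bad}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total assigned read pairs per sample (summary rows excluded)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.special.copy())

    def subset_samples(self, sample_ids) -> "CountMatrix":
        cols = list(sample_ids)
        return CountMatrix(self.counts[cols], self.special[cols] if len(self.special.columns) else self.special)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.special.equals(other.special)


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix with its unit recorded (CPM/FPKM/LOG2)."""

    values: pd.DataFrame
    unit: str

    _UNITS = ("CPM", "FPKM", "LOG2")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unit must be one of {self._UNITS}, got {self.unit!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.unit in ("CPM", "FPKM") and (arr < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet (sample_id, station, outcome) and return it.

    Outcomes are restricted to AI_PREGNANT / NB_PREGNANT / NOT_PREGNANT and
    sample ids must be unique.
    """
    required = {"sample_id", "station", "outcome"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("sample table is empty")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    unknown = set(table["outcome"]) - set(OUTCOMES)
    if unknown:
        raise ValueError(
            f"unknown outcome labels {sorted(unknown)}; allowed: {OUTCOMES}"
        )
    return table.reset_index(drop=True)


def validate_gene_lengths(lengths: pd.Series) -> pd.Series:
    """Validate a gene_id -> length (bp) mapping; lengths must be >= 1."""
    if lengths.index.has_duplicates:
        raise ValueError("duplicate gene ids in length table")
    vals = lengths.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or (vals < 1).any():
        raise ValueError("gene lengths must be integers >= 1")
    return lengths.astype(np.int64)
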