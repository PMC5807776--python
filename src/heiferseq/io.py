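"""Readers and writers for count files, sample sheets and gene lengths.

Count files follow the htseq-count output dialect: two tab-separated
columns (feature id, count), no header, with five "__"-prefixed summary
rows trailing the gene rows. One file per sample.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .containers import (
    CountMatrix,
    HTSEQ_SPECIAL_ROWS,
    validate_gene_lengths,
    validate_sample_table,
)


def _read_one_htseq(path) -> pd.Series:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["id", "count"], dtype={"id": str}
    )
    if df.empty:
        raise ValueError(f"{path}: empty count file")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    counts = pd.to_numeric(df["count"], errors="raise")
    if not (counts == counts.round()).all():
        raise ValueError(f"{path}: non-integer count encountered")
    if (counts < 0).any():
        raise ValueError(f"{path}: negative count encountered")
    return pd.Series(counts.astype("int64").to_numpy(), index=df["id"].to_numpy())


def read_htseq_counts(paths: Sequence, sample_ids: Sequence[str]) -> CountMatrix:
    """Assemble a CountMatrix from per-sample htseq-count files.

    The gene order of the first file is the reference order; every other
    file must contain exactly the same gene set (any order). "__"-prefixed
    rows are diverted to the summary-counter table, never counted as genes.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("one path per sample id required")
    if len(paths) == 0:
        raise ValueError("no count files given")
    gene_cols: dict[str, pd.Series] = {}
    special_cols: dict[str, pd.Series] = {}
    ref_genes: pd.Index | None = None
    for path, sid in zip(paths, sample_ids):
        col = _read_one_htseq(path)
        is_special = col.index.str.startswith("__")
        special_cols[sid] = col[is_special]
        genes = col[~is_special]
        if ref_genes is None:
            ref_genes = genes.index
        else:
            if set(genes.index) != set(ref_genes):
                only_here = sorted(set(genes.index) - set(ref_genes))
                only_ref = sorted(set(ref_genes) - set(genes.index))
                raise ValueError(
                    f"{path}: gene set differs from first file; "
                    f"extra={only_here[:10]}, missing={only_ref[:10]}"
                )
            genes = genes.reindex(ref_genes)
        gene_cols[sid] = genes
    counts = pd.DataFrame(gene_cols, index=ref_genes, columns=list(sample_ids))
    special = pd.DataFrame(special_cols, columns=list(sample_ids)).fillna(0).astype(
        "int64"
    )
    return CountMatrix(counts, special)


def write_counts(matrix: CountMatrix, directory) -> list[Path]:
    """Write one htseq-dialect file per sample as ``<sample_id>.counts.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid in matrix.sample_ids:
        path = directory / f"{sid}.counts.tsv"
        genes = matrix.counts[sid]
        special = matrix.special[sid] if sid in matrix.special.columns else pd.Series(dtype="int64")
        # keep canonical ordering of the five summary rows at the end
        ordered_special = [r for r in HTSEQ_SPECIAL_ROWS if r in special.index]
        ordered_special += [r for r in special.index if r not in HTSEQ_SPECIAL_ROWS]
        with open(path, "w", encoding="utf-8") as fh:
            for gid, val in genes.items():
                fh.write(f"{gid}\t{val}\n")
            for row in ordered_special:
                fh.write(f"{row}\t{special[row]}\n")
        paths.append(path)
    return paths


def read_sample_table(path) -> pd.DataFrame:
    """Read a tab-separated sample sheet with columns sample_id, station, outcome."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty sample table")
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path) -> None:
    validate_sample_table(table).to_csv(path, sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    """Read a tab-separated gene_id -> length (bp) table."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty gene length table")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "length"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, length")
    return validate_gene_lengths(pd.Series(df["length"].to_numpy(), index=df["gene_id"].to_numpy(), name="length"))


def write_gene_lengths(lengths: pd.Series, path) -> None:
    validate_gene_lengths(lengths)
    pd.DataFrame({"gene_id": lengths.index, "length": lengths.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_qpcr_table(path) -> pd.DataFrame:
    """Read a long-format qPCR table with columns sample_id, gene_id, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    if not {"sample_id", "gene_id", "ct"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, gene_id, ct")
    if df.duplicated(["sample_id", "gene_id"]).any():
        raise ValueError(f"{path}: more than one CT per sample x gene")
    if (df["ct"] <= 0).any():
        raise ValueError(f"{path}: CT values must be positive")
    return df


def write_qpcr_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
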