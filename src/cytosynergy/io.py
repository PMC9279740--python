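"""TSV readers and writers for counts, metadata, pair tables, and results.

All tables are UTF-8 TSV with '.' decimals; writers emit deterministic column
and row order (rows sorted by gene id where applicable) so outputs diff
cleanly between runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count table (first column gene ids, header row).

    Every cell must be a non-negative integer; violations are reported with
    the offending gene and sample. Duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate gene ids: {dups}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-integer or negative count for gene {gene!r}, "
                f"sample {col!r}"
            )
        out[col] = vals.astype(np.int64)
    result = pd.DataFrame(out, index=df.index)
    result.index.name = "gene_id"
    return result


def write_counts(counts: pd.DataFrame, path) -> None:
    counts = counts.sort_index()
    counts.index.name = "gene_id"
    counts.to_csv(path, sep="\t")


def read_metadata(path) -> pd.Series:
    """Read the sample metadata table (columns ``sample_id``, ``condition``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata must have a {col!r} column")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df["sample_id"][df["sample_id"].duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids: {dups}")
    return pd.Series(df["condition"].to_numpy(), index=df["sample_id"],
                     name="condition")


def write_metadata(conditions: pd.Series, path) -> None:
    pd.DataFrame(
        {"sample_id": conditions.index, "condition": conditions.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_metadata(metadata_path))


def write_count_matrix(matrix: CountMatrix, counts_path, metadata_path) -> None:
    write_counts(matrix.counts, counts_path)
    write_metadata(matrix.conditions, metadata_path)


def read_pairs(path) -> pd.DataFrame:
    """Read a ligand–receptor pair table (columns ``ligand``, ``receptor``,
    optional ``pair`` label); duplicate pairs are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"{path}: pair table must have a {col!r} column")
    if df[["ligand", "receptor"]].isna().any().any():
        raise ValueError(f"{path}: empty ligand or receptor id")
    key = df["ligand"].str.lower() + "\t" + df["receptor"].str.lower()
    if key.duplicated().any():
        raise ValueError(f"{path}: duplicate ligand-receptor pairs")
    return df


def write_table(df: pd.DataFrame, path, sort_by: str | None = "gene_id") -> None:
    """Write a result table with deterministic row order."""
    if sort_by is not None and sort_by in df.columns:
        df = df.sort_values(sort_by, kind="stable")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
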