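"""File adapters: counts (TSV / MatrixMarket), covariates, results, mappings.

All tables are UTF-8; counts are written features-in-rows with a header of
sample ids. The MatrixMarket path writes the coordinate .mtx plus sidecar
``<stem>.rownames.txt`` / ``<stem>.colnames.txt`` files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_covariates_csv",
    "write_covariates_csv",
    "read_table_tsv",
    "write_table_tsv",
    "read_mapping_tsv",
    "map_transcripts_to_genes",
]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate feature or sample identifiers")
    values = df.to_numpy()
    if (values < 0).any() or not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64).rename_axis("feature_id")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("feature_id").to_csv(path, sep="\t")


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    spio.mmwrite(path, sparse.coo_matrix(counts.to_numpy()))
    path.with_suffix(".rownames.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    path.with_suffix(".colnames.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(path) -> pd.DataFrame:
    path = Path(path)
    m = spio.mmread(path).toarray().astype(np.int64)
    rows = path.with_suffix(".rownames.txt").read_text().splitlines()
    cols = path.with_suffix(".colnames.txt").read_text().splitlines()
    if m.shape != (len(rows), len(cols)):
        raise ValueError(f"{path}: matrix shape {m.shape} does not match name files")
    return pd.DataFrame(m, index=rows, columns=cols).rename_axis("feature_id")


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    return df.rename_axis("sample_id")


def write_covariates_csv(table: pd.DataFrame, path) -> None:
    table.rename_axis("sample_id").to_csv(path)


def read_table_tsv(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_mapping_tsv(path) -> pd.DataFrame:
    """Transcript -> gene mapping with columns ``transcript_id, gene_id``."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: mapping needs columns {sorted(required)}")
    return df[["transcript_id", "gene_id"]]


def map_transcripts_to_genes(
    values: pd.Series, mapping: pd.DataFrame, rule: str = "max_abs"
) -> pd.DataFrame:
    """Collapse transcript-level scores to gene level.

    ``max_abs`` (default) keeps, per gene, the signed value of largest
    magnitude across its transcripts; ``mean`` averages them. Unmapped
    transcripts are dropped (their count is in ``.attrs['n_unmapped']``).
    Returns a frame indexed by gene with columns ``value`` and ``source``
    (the transcript contributing the value; for ``mean``, the count).
    """
    if rule not in {"max_abs", "mean"}:
        raise ValueError("rule must be 'max_abs' or 'mean'")
    m = mapping.set_index("transcript_id")["gene_id"]
    shared = values.index.intersection(m.index)
    n_unmapped = len(values) - len(shared)
    df = pd.DataFrame({"value": values.loc[shared], "gene_id": m.loc[shared]})
    if rule == "max_abs":
        idx = df.groupby("gene_id")["value"].apply(lambda s: s.abs().idxmax())
        out = pd.DataFrame({"value": df.loc[idx, "value"].to_numpy(), "source": idx.to_numpy()},
                           index=idx.index)
    else:
        grouped = df.groupby("gene_id")["value"]
        out = pd.DataFrame({"value": grouped.mean(), "source": grouped.size().astype(str) + " transcripts"})
    out.index.name = "gene_id"
    out.attrs["n_unmapped"] = n_unmapped
    return out
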