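"""Read-count matrix container and TSV ingestion.

The count table format is the one produced by per-gene read counting:
first column gene id, header row of sample names, non-negative integer
counts. Replicate columns may optionally be aggregated before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Wraps a pandas DataFrame (index = gene ids, columns = sample ids) and
    enforces the count-table contract on construction: unique gene and
    sample ids, no missing values, integral non-negative entries.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        if df.isna().any().any():
            rows, cols = np.where(df.isna())
            gene, sample = df.index[rows[0]], df.columns[cols[0]]
            raise ValueError(f"missing count at gene {gene!r}, sample {sample!r}")
        arr = df.to_numpy()
        if arr.size == 0:
            self.data = df.astype(np.int64)
            return
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("negative counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.data = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.data[sample_id]

    def to_tsv(self, path: str | Path, gene_column: str = "gene_id") -> None:
        self.data.rename_axis(gene_column).to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a headered TSV count table (gene-id column first) into a
    validated CountMatrix.

    Raises ``ValueError`` on duplicate gene ids (naming the id), missing
    values (naming row and column), negative or non-integral entries.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    return CountMatrix(df)


def aggregate_replicates(
    matrix: CountMatrix, groups: dict[str, list[str]], how: str = "sum"
) -> CountMatrix:
    """Collapse replicate columns into one column per condition.

    ``groups`` maps condition name -> list of replicate column names.
    ``how`` is ``sum`` (counts are additive when replicates were pooled)
    or ``mean`` (rounded to the nearest integer count).
    """
    if how not in ("sum", "mean"):
        raise ValueError("how must be 'sum' or 'mean'")
    cols = {}
    for cond, reps in groups.items():
        sub = matrix.data[list(reps)]
        agg = sub.sum(axis=1) if how == "sum" else sub.mean(axis=1).round()
        cols[cond] = agg
    return CountMatrix(pd.DataFrame(cols, index=matrix.data.index))


def infer_replicate_groups(
    sample_ids: list[str], sep: str = "_rep"
) -> dict[str, list[str]]:
    """Group sample column names by the prefix before ``sep``.

    Columns without the separator form their own singleton group.
    """
    groups: dict[str, list[str]] = {}
    for s in sample_ids:
        cond = s.split(sep)[0] if sep in s else s
        groups.setdefault(cond, []).append(s)
    return groups
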