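"""Per-sample ranking and top-fraction intersection across conditions.

A gene is called a constitutive high-expresser when it sits in the top
``top_fraction`` of genes, ranked by raw read counts, in every sampled
condition. Ranking deliberately uses raw counts rather than length- or
depth-normalised values; an optional CPM mode exists for sensitivity
analysis but is off by default. Raw-count ranking carries a gene-length
bias which is noted, not corrected.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .counts import CountMatrix, aggregate_replicates, infer_replicate_groups


@dataclass
class SelectionParams:
    """Parameters of the top-fraction intersection screen.

    Parameters
    ----------
    top_fraction : float
        Fraction of genes retained per sample, default 0.03 ("top 3%").
    min_samples : int or None
        Number of samples a gene must qualify in; None means all samples.
    aggregation : {"sum", "mean", "none"}
        How replicate columns are collapsed before ranking. Default "sum":
        when replicates were physically pooled before sequencing the
        columns are condition-level already and aggregation is a no-op.
    boundary : {"truncate", "ties"}
        Cutoff behaviour when counts tie at rank k: "truncate" keeps
        exactly k genes (stable order: descending count, ascending id);
        "ties" also keeps every gene tied with the k-th.
    cpm : bool
        Rank on counts-per-million instead of raw counts.
    replicate_sep : str
        Column-name separator used to infer replicate groups.
    """

    top_fraction: float = 0.03
    min_samples: int | None = None
    aggregation: str = "sum"
    boundary: str = "truncate"
    cpm: bool = False
    replicate_sep: str = "_rep"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.aggregation not in ("sum", "mean", "none"):
            raise ValueError("aggregation must be 'sum', 'mean' or 'none'")
        if self.boundary not in ("truncate", "ties"):
            raise ValueError("boundary must be 'truncate' or 'ties'")


@dataclass
class SelectionResult:
    """Per-sample top sets, their intersection, and ranking bookkeeping."""

    per_sample_top: dict[str, list[str]]
    intersection: set[str]
    cutoff_size_per_sample: int
    ranking_table: pd.DataFrame  # genes x samples, rank 1 = highest count
    params: SelectionParams = field(default_factory=SelectionParams)

    def report(self) -> pd.DataFrame:
        """Long-form report: per-sample rank, qualifying flag, intersection flag."""
        df = self.ranking_table.copy()
        for s, top in self.per_sample_top.items():
            df[f"{s}_in_top"] = df.index.isin(top)
        df["in_intersection"] = df.index.isin(self.intersection)
        return df

    def to_json(self, path: str | Path) -> None:
        """Per-sample set JSON for Venn-style reporting."""
        payload = {
            "per_sample_top": {s: sorted(g) for s, g in self.per_sample_top.items()},
            "intersection": sorted(self.intersection),
            "cutoff_size_per_sample": self.cutoff_size_per_sample,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _ranking_values(matrix: CountMatrix, cpm: bool) -> pd.DataFrame:
    df = matrix.data.astype(float)
    if cpm:
        totals = df.sum(axis=0)
        totals = totals.replace(0, 1)  # empty sample ranks degenerately
        df = df / totals * 1e6
    return df


def rank_genes(
    matrix: CountMatrix, sample: str, cpm: bool = False
) -> list[str]:
    """Genes of one sample sorted by descending count, rank 1 = highest.

    Ties are broken by ascending gene id, so the ordering is a total order
    and reproducible across runs and row shufflings.
    """
    values = _ranking_values(matrix, cpm)[
        matrix.sample(sample).name
    ]
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return order


def cutoff_size(n_genes: int, top_fraction: float) -> int:
    """k = ceiling(top_fraction * n_genes); ceiling keeps the top set
    non-empty for any non-empty input."""
    return math.ceil(top_fraction * n_genes)


def top_fraction_set(
    matrix: CountMatrix, sample: str, params: SelectionParams
) -> set[str]:
    """The top-k gene set of one sample, k = ceiling(top_fraction * n)."""
    order = rank_genes(matrix, sample, cpm=params.cpm)
    k = cutoff_size(matrix.n_genes, params.top_fraction)
    if k == 0:
        warnings.warn(f"empty count matrix: top set of {sample!r} is empty")
        return set()
    top = order[:k]
    if params.boundary == "ties" and k < len(order):
        values = _ranking_values(matrix, params.cpm)[sample]
        threshold = values[order[k - 1]]
        top = [g for g in order if values[g] > threshold] + [
            g for g in order if values[g] == threshold
        ]
    return set(top)


def _maybe_aggregate(matrix: CountMatrix, params: SelectionParams) -> CountMatrix:
    if params.aggregation == "none":
        return matrix
    groups = infer_replicate_groups(matrix.sample_ids, params.replicate_sep)
    if all(len(v) == 1 for v in groups.values()):
        return matrix
    return aggregate_replicates(matrix, groups, how=params.aggregation)


def intersect_top_sets(
    matrix: CountMatrix, params: SelectionParams | None = None
) -> SelectionResult:
    """Rank each sample, take its top fraction, and intersect across samples.

    The intersection holds the genes qualifying in at least ``min_samples``
    samples (default: all), i.e. the constitutive high-expressers.
    """
    params = params or SelectionParams()
    matrix = _maybe_aggregate(matrix, params)
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    need = params.min_samples if params.min_samples is not None else matrix.n_samples
    if not (1 <= need <= matrix.n_samples):
        raise ValueError(f"min_samples must be in [1, {matrix.n_samples}]")

    k = cutoff_size(matrix.n_genes, params.top_fraction)
    per_sample_top: dict[str, list[str]] = {}
    ranks = {}
    for s in matrix.sample_ids:
        order = rank_genes(matrix, s, cpm=params.cpm)
        ranks[s] = pd.Series(
            range(1, len(order) + 1), index=order, dtype=int
        )
        top = top_fraction_set(matrix, s, params)
        # keep ranked order within the top set
        per_sample_top[s] = [g for g in order if g in top]

    qualify_counts: dict[str, int] = {}
    for s, top in per_sample_top.items():
        for g in top:
            qualify_counts[g] = qualify_counts.get(g, 0) + 1
    intersection = {g for g, c in qualify_counts.items() if c >= need}

    ranking_table = pd.DataFrame(
        {s: ranks[s].reindex(matrix.gene_ids) for s in matrix.sample_ids},
        index=matrix.gene_ids,
    )
    return SelectionResult(
        per_sample_top=per_sample_top,
        intersection=intersection,
        cutoff_size_per_sample=k,
        ranking_table=ranking_table,
        params=params,
    )
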