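"""Strand-aware upstream intergenic region extraction on circular replicons.

The promoter region of a candidate gene is defined positionally: the
intergenic span between the gene's 5' boundary and the nearest annotated
feature boundary on its 5' side, irrespective of the neighbour's strand
(the neighbour's identity is recorded for auditing). Overlapping or
abutting neighbours yield a length-0 region, never a negative one.
Regions shorter than ``min_length`` (default 100 bp) are excluded from
cloning candidacy: a 100 bp region is retained, 99 bp is not.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

from .annotation import GeneRecord, GenomeAnnotation, reverse_complement

DEFAULT_MIN_LENGTH = 100


@dataclass
class PromoterRegion:
    """An upstream intergenic interval for one candidate gene.

    ``interval`` is (start, end) in forward replicon coordinates, 0-based
    half-open; on a circular replicon start > end means the region wraps
    across the origin. ``strand`` is the downstream (candidate) gene's
    strand; ``sequence``, when present, is oriented 5'->3' relative to
    that gene (reverse-complemented for minus-strand genes).
    """

    promoter_id: str
    gene_id: str
    upstream_feature_id: str | None
    interval: tuple[int, int]
    strand: str
    length: int
    sequence: str | None = None
    passed_filter: bool | None = None
    truncated_at_edge: bool = False
    upstream_strand: str | None = None


def promoter_id_for(gene: GeneRecord) -> str:
    """Promoter naming: 'P' + trailing digits of the locus tag (or gene id),
    e.g. locus tag ending in 12445 -> P12445."""
    source = gene.locus_tag or gene.gene_id
    m = re.search(r"(\d+)$", source)
    return f"P{m.group(1)}" if m else f"P_{source}"


def _circular_upstream(
    annotation: GenomeAnnotation, gene: GeneRecord
) -> tuple[int, int, int, GeneRecord | None, bool]:
    """Return (start, end, length, upstream_feature, truncated)."""
    others = [g for g in annotation.genes if g.gene_id != gene.gene_id]
    L = annotation.length
    plus = gene.strand == "+"
    anchor = gene.start if plus else gene.end  # the gene's 5' boundary

    # a neighbour covering the anchor position collapses the region to 0
    overlapping = [
        f
        for f in others
        if (f.start < anchor < f.end)
    ]
    if overlapping:
        # deepest intrusion wins; deterministic tie-break on id
        if plus:
            up = max(overlapping, key=lambda f: (f.end, f.gene_id))
        else:
            up = min(overlapping, key=lambda f: (f.start, f.gene_id))
        return anchor, anchor, 0, up, False

    if annotation.circular:
        # The candidate 5' boundaries are every other feature's 3'-facing
        # edge plus the gene's own far end: with no (or only downstream)
        # neighbours the walk wraps the whole circle and stops at the gene
        # itself, giving length L - len(gene).
        if plus:
            candidates = [(f, f.end % L) for f in others] + [(gene, gene.end % L)]
            up, start = min(
                candidates, key=lambda fb: ((anchor - fb[1]) % L, fb[0].gene_id)
            )
            length = (anchor - start) % L
            return start, anchor, length, up, False
        a = anchor % L  # a gene ending exactly at the origin wraps to 0
        candidates = [(f, f.start) for f in others] + [(gene, gene.start)]
        up, end = min(
            candidates, key=lambda fb: ((fb[1] - a) % L, fb[0].gene_id)
        )
        length = (end - a) % L
        return a, end, length, up, False

    if not others:
        # linear: truncate at the replicon edge
        if plus:
            return 0, gene.start, gene.start, None, True
        return gene.end, L, L - gene.end, None, True

    # linear replicon
    if plus:
        left = [f for f in others if f.end <= anchor]
        if not left:
            return 0, anchor, anchor, None, True
        up = max(left, key=lambda f: (f.end, f.gene_id))
        return up.end, anchor, anchor - up.end, up, False
    right = [f for f in others if f.start >= anchor]
    if not right:
        return anchor, L, L - anchor, None, True
    up = min(right, key=lambda f: (f.start, f.gene_id))
    return anchor, up.start, up.start - anchor, up, False


def upstream_intergenic(
    annotation: GenomeAnnotation, gene_id: str
) -> PromoterRegion:
    """Compute the (unfiltered) upstream intergenic region of one gene.

    For a plus-strand gene the region runs from the nearest feature
    boundary left of the gene's start to the start itself; for a
    minus-strand gene, from the gene's end to the nearest feature boundary
    on its right. Circular replicons wrap across the origin; on a linear
    replicon a gene with no 5' neighbour is truncated at the edge and
    flagged.
    """
    gene = annotation.gene(gene_id)
    start, end, length, up, truncated = _circular_upstream(annotation, gene)
    sequence = None
    if annotation.sequence is not None:
        fwd = annotation.slice_sequence(start, end) if length > 0 else ""
        sequence = fwd if gene.strand == "+" else reverse_complement(fwd)
    return PromoterRegion(
        promoter_id=promoter_id_for(gene),
        gene_id=gene.gene_id,
        upstream_feature_id=up.gene_id if up else None,
        interval=(start, end),
        strand=gene.strand,
        length=length,
        sequence=sequence,
        truncated_at_edge=truncated,
        upstream_strand=up.strand if up else None,
    )


def extract_promoters(
    annotation: GenomeAnnotation, gene_ids
) -> list[PromoterRegion]:
    """Upstream regions for a collection of candidate genes (stable order)."""
    return [upstream_intergenic(annotation, g) for g in gene_ids]


def filter_promoters(
    regions: list[PromoterRegion], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[PromoterRegion], list[PromoterRegion]]:
    """Partition regions into (retained, excluded) by the length filter.

    Exclusion means *shorter than* ``min_length``: a region of exactly
    ``min_length`` bp is retained. The partition is exhaustive and
    disjoint, and each region's ``passed_filter`` flag is set.
    """
    retained, excluded = [], []
    for r in regions:
        r.passed_filter = r.length >= min_length
        (retained if r.passed_filter else excluded).append(r)
    return retained, excluded


# ---------------------------------------------------------------------------
# Exports


def export_promoters(
    regions: list[PromoterRegion],
    out_prefix: str | Path,
    replicon_id: str = "replicon",
    fasta: bool = True,
) -> dict[str, Path]:
    """Write BED, FASTA and a summary TSV for a set of promoter regions.

    BED is 0-based half-open with the downstream gene's strand in the
    strand column; FASTA ids are promoter ids and sequences are
    gene-oriented. Returns the mapping of format -> written path.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if not regions:
        warnings.warn("no promoter regions to export; writing empty files")
    if fasta and any(r.sequence is None and r.length > 0 for r in regions):
        missing = [r.promoter_id for r in regions if r.sequence is None]
        raise ValueError(f"FASTA requested but sequence missing for {missing}")

    paths = {}
    bed_path = out_prefix.with_suffix(".bed")
    with open(bed_path, "w") as fh:
        for r in regions:
            start, end = r.interval
            fh.write(
                f"{replicon_id}\t{start}\t{end}\t{r.promoter_id}\t.\t{r.strand}\n"
            )
    paths["bed"] = bed_path

    if fasta:
        fa_path = out_prefix.with_suffix(".fa")
        with open(fa_path, "w") as fh:
            for r in regions:
                fh.write(f">{r.promoter_id} gene={r.gene_id} length={r.length}\n")
                seq = r.sequence or ""
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths["fasta"] = fa_path

    tsv_path = out_prefix.with_suffix(".tsv")
    with open(tsv_path, "w") as fh:
        fh.write(
            "promoter_id\tgene_id\tupstream_feature\tstart\tend\tstrand\t"
            "length\tpassed_filter\n"
        )
        for r in regions:
            fh.write(
                f"{r.promoter_id}\t{r.gene_id}\t{r.upstream_feature_id or '.'}\t"
                f"{r.interval[0]}\t{r.interval[1]}\t{r.strand}\t{r.length}\t"
                f"{r.passed_filter}\n"
            )
    paths["tsv"] = tsv_path
    return paths
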