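"""Genome annotation containers and GenBank/GFF3/FASTA input-output.

All coordinates are held internally as 0-based half-open intervals on the
forward strand (``start < end``), the BED convention. GenBank and GFF3 use
1-based inclusive coordinates; conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

# Feature classes that count as promoter-bounding neighbours. Non-coding RNA
# genes bound intergenic regions just as CDS genes do (a tmRNA promoter is a
# perfectly good promoter candidate), so they are first-class records here.
FEATURE_TYPES = ("gene", "CDS", "rRNA", "tRNA", "tmRNA", "ncRNA")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature on a replicon, 0-based half-open."""

    gene_id: str
    start: int
    end: int
    strand: str
    locus_tag: str = ""
    product: str = ""
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed coordinates for {self.gene_id!r}: "
                f"({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand of {self.gene_id!r} must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """An annotated replicon: ordered gene intervals plus optional sequence.

    Parameters
    ----------
    replicon_id : str
        Sequence identifier (e.g. an accession).
    length : int
        Replicon length in bp.
    genes : list of GeneRecord
        Stored sorted by start coordinate; identifiers must be unique.
    circular : bool
        Whether intervals may wrap across the origin (bacterial chromosomes
        and plasmids usually do).
    sequence : str or None
        Forward-strand nucleotide sequence; optional for interval-only use.
    """

    replicon_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("replicon length must be positive")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id!r} extends past replicon end "
                    f"({g.end} > {self.length})"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != stated length {self.length}"
            )
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def slice_sequence(self, start: int, end: int) -> str:
        """Forward-strand sequence of [start, end), wrapping the origin when
        ``start > end`` on a circular replicon."""
        if self.sequence is None:
            raise ValueError("annotation carries no sequence")
        if start <= end:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("wrapped interval on a linear replicon")
        return self.sequence[start:] + self.sequence[:end]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Readers


def _from_seqrecord(rec: SeqRecord) -> GenomeAnnotation:
    """Normalise a Biopython GenBank record into a GenomeAnnotation."""
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    # genes first so a CDS with the same locus_tag does not duplicate it
    for ftype in FEATURE_TYPES:
        for feat in rec.features:
            if feat.type != ftype:
                continue
            q = feat.qualifiers
            locus = q.get("locus_tag", [""])[0]
            gid = locus or q.get("gene", [""])[0] or q.get("ID", [""])[0]
            if not gid:
                gid = f"{ftype}_{int(feat.location.start)}_{int(feat.location.end)}"
            if gid in seen:
                continue
            seen.add(gid)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    locus_tag=locus,
                    product=q.get("product", [""])[0],
                    feature_type=ftype,
                )
            )
    topology = rec.annotations.get("topology", "circular")
    return GenomeAnnotation(
        replicon_id=rec.id,
        length=len(rec.seq),
        genes=genes,
        circular=topology != "linear",
        sequence=str(rec.seq) if len(rec.seq) else None,
    )


def _read_gff3(
    path: str | Path, fasta: str | Path | None, circular: bool
) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    sequence = None
    replicon_id = None
    length = None
    if fasta is not None:
        rec = next(SeqIO.parse(str(fasta), "fasta"))
        sequence = str(rec.seq)
        replicon_id = rec.id
        length = len(sequence)

    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for ftype in FEATURE_TYPES:
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            feats = []
        for f in feats:
            gid = f.attributes.get("ID", [f.id])[0]
            if gid in seen:
                continue
            seen.add(gid)
            if replicon_id is None:
                replicon_id = f.seqid
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    start=f.start - 1,
                    end=f.end,
                    strand="-" if f.strand == "-" else "+",
                    locus_tag=f.attributes.get("locus_tag", [""])[0],
                    product=f.attributes.get("product", [""])[0],
                    feature_type=ftype,
                )
            )
    # sequence-region pragma carries the length when no FASTA is given
    if length is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    replicon_id = replicon_id or parts[1]
                    length = int(parts[3])
                    break
    if length is None:
        length = max(g.end for g in genes) if genes else 1
    return GenomeAnnotation(
        replicon_id=replicon_id or "unknown",
        length=length,
        genes=genes,
        circular=circular,
        sequence=sequence,
    )


def read_annotation(
    path: str | Path,
    format: str | None = None,
    fasta: str | Path | None = None,
    circular: bool = True,
) -> GenomeAnnotation:
    """Read a GenBank flat file or a GFF3 (+ optional FASTA) annotation.

    Input 1-based inclusive coordinates are converted to the internal
    0-based half-open convention on read.

    Parameters
    ----------
    path : path
        GenBank (.gb/.gbk/.gbff) or GFF3 (.gff/.gff3) file.
    format : {"genbank", "gff3"}, optional
        Inferred from the file extension when omitted.
    fasta : path, optional
        Companion FASTA for GFF3 input (supplies the sequence).
    circular : bool
        Replicon topology for GFF3 input; GenBank carries its own topology.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "genbank" if suffix in (".gb", ".gbk", ".gbff", ".genbank") else "gff3"
    if format == "genbank":
        rec = next(SeqIO.parse(str(path), "genbank"))
        return _from_seqrecord(rec)
    if format == "gff3":
        return _read_gff3(path, fasta, circular)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Writers


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {annotation.replicon_id} 1 {annotation.length}\n"
        )
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            if g.locus_tag:
                attrs += f";locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{annotation.replicon_id}\tpromscreen\t{g.feature_type}\t"
                f"{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_fasta(annotation: GenomeAnnotation, path: str | Path) -> None:
    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    rec = SeqRecord(
        Seq(annotation.sequence), id=annotation.replicon_id, description=""
    )
    SeqIO.write([rec], str(path), "fasta")


def write_genbank(annotation: GenomeAnnotation, path: str | Path) -> None:
    if annotation.sequence is None:
        raise ValueError("GenBank output requires a sequence")
    features = []
    for g in annotation.genes:
        qualifiers = {"locus_tag": [g.locus_tag or g.gene_id]}
        if g.product:
            qualifiers["product"] = [g.product]
        features.append(
            SeqFeature(
                FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                type=g.feature_type,
                qualifiers=qualifiers,
            )
        )
    rec = SeqRecord(
        Seq(annotation.sequence),
        id=annotation.replicon_id,
        name=annotation.replicon_id[:16].replace(".", "_"),
        description="synthetic annotated replicon",
        features=features,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if annotation.circular else "linear"
    SeqIO.write([rec], str(path), "genbank")
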