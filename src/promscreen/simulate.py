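"""Synthetic study bundles with known ground truth.

Emulates the study design the screen is built for: an annotated circular
bacterial replicon with strand-mixed, non-overlapping genes and a mixture
of short (< 100 bp) and long intergenic gaps; per-condition read-count
columns over four samples (two time points in two media) in which a
planted subset of genes is uniformly in the top percentile of every
sample (constitutive) while decoy genes are top-ranked only in a strict
subset of samples (condition-specific); and assay measurement tables
whose known true parameters the quantitation formulas must recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GenomeAnnotation
from .counts import CountMatrix

SHORT_GAP_THRESHOLD = 100
ALPHABET = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study bundle.

    Defaults give 200 genes over 4 samples with 5 planted constitutive
    genes and 5 condition-specific decoys; background counts are
    negative-binomial with mean 50, constitutive genes 1000x that, which
    puts every constitutive gene in the top percentile of every sample
    essentially surely. Decoys are high (200x background) only in their
    assigned samples; keeping them below the constitutive mean means a
    surplus of decoys in one sample can never push a constitutive gene
    out of the top fraction.
    """

    genome_length: int = 250_000
    n_genes: int = 200
    n_samples: int = 4
    n_constitutive: int = 5
    n_conditional: int = 5
    frac_short_gap: float = 0.3
    background_mean: float = 50.0
    high_mean: float = 50_000.0
    conditional_mean: float = 10_000.0
    nb_dispersion: float = 0.01  # var = m + dispersion * m^2
    replicates: int = 1
    n_constitutive_short: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 0:
            raise ValueError("genome_length must be positive, n_genes >= 0")
        if self.n_constitutive + self.n_conditional >= max(self.n_genes, 1):
            if self.n_genes > 0:
                raise ValueError(
                    "n_constitutive + n_conditional must be < n_genes"
                )
        if not (0 <= self.frac_short_gap <= 1):
            raise ValueError("frac_short_gap must be in [0, 1]")
        if self.n_samples < 1 or self.replicates < 1:
            raise ValueError("need >= 1 sample and >= 1 replicate")
        if self.n_constitutive_short is not None and not (
            0 <= self.n_constitutive_short <= self.n_constitutive
        ):
            raise ValueError("n_constitutive_short must be <= n_constitutive")


@dataclass
class GroundTruth:
    """Which genes were planted, and which have a short upstream gap."""

    constitutive_ids: set[str] = field(default_factory=set)
    conditional_ids: set[str] = field(default_factory=set)
    short_gap_ids: set[str] = field(default_factory=set)
    conditional_samples: dict[str, list[str]] = field(default_factory=dict)
    upstream_gap: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.short_gap_ids <= self.constitutive_ids:
            raise ValueError("short_gap_ids must be a subset of constitutive_ids")
        if self.constitutive_ids & self.conditional_ids:
            raise ValueError("constitutive and conditional ids must be disjoint")

    @property
    def expected_retained(self) -> set[str]:
        """The genes the full screen should recover: constitutive genes
        whose upstream intergenic gap passes the length filter."""
        return self.constitutive_ids - self.short_gap_ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "constitutive_ids": sorted(self.constitutive_ids),
            "conditional_ids": sorted(self.conditional_ids),
            "short_gap_ids": sorted(self.short_gap_ids),
            "conditional_samples": self.conditional_samples,
            "upstream_gap": self.upstream_gap,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            constitutive_ids=set(d["constitutive_ids"]),
            conditional_ids=set(d["conditional_ids"]),
            short_gap_ids=set(d["short_gap_ids"]),
            conditional_samples=d.get("conditional_samples", {}),
            upstream_gap=d.get("upstream_gap", {}),
        )


def _gene_id(i: int) -> str:
    return f"SYN_{i + 1:05d}"


# ---------------------------------------------------------------------------
# Genome generation


def _draw_layout(spec: SyntheticSpec, rng: np.random.Generator):
    """Gene lengths and intergenic gaps; gap i precedes gene i."""
    n = spec.n_genes
    lengths = rng.integers(200, 1201, size=n)
    short = rng.random(n) < spec.frac_short_gap
    gaps = np.where(
        short,
        rng.integers(10, SHORT_GAP_THRESHOLD, size=n),
        rng.integers(SHORT_GAP_THRESHOLD, 601, size=n),
    )
    return lengths, gaps


def generate_genome(spec: SyntheticSpec) -> GenomeAnnotation:
    """A circular replicon with non-overlapping genes on random strands.

    Gap lengths are drawn from a two-part mixture: a fraction
    ``frac_short_gap`` below 100 bp (uniform 10..99) and the rest at or
    above it (uniform 100..600). Any length left over after packing is
    absorbed into the origin-wrap gap. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    if n == 0:
        seq = "".join(rng.choice(ALPHABET, size=spec.genome_length))
        return GenomeAnnotation(
            replicon_id="synthetic_1",
            length=spec.genome_length,
            genes=[],
            circular=True,
            sequence=seq,
        )
    lengths, gaps = _draw_layout(spec, rng)
    if int(lengths.sum()) >= spec.genome_length:
        raise ValueError(
            f"infeasible packing: total gene span {int(lengths.sum())} >= "
            f"genome length {spec.genome_length}"
        )
    total = int(lengths.sum() + gaps.sum())
    if total > spec.genome_length:
        raise ValueError(
            f"infeasible packing: genes + gaps span {total} > "
            f"genome length {spec.genome_length}"
        )
    strands = rng.choice(["+", "-"], size=n)
    genes = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        genes.append(
            GeneRecord(
                gene_id=_gene_id(i),
                start=pos,
                end=pos + int(lengths[i]),
                strand=str(strands[i]),
                locus_tag=f"SYN_RS{(i + 1) * 5:05d}",
                product="hypothetical protein",
                feature_type="gene",
            )
        )
        pos += int(lengths[i])
    seq = "".join(rng.choice(ALPHABET, size=spec.genome_length))
    return GenomeAnnotation(
        replicon_id="synthetic_1",
        length=spec.genome_length,
        genes=genes,
        circular=True,
        sequence=seq,
    )


def upstream_gaps(annotation: GenomeAnnotation) -> dict[str, int]:
    """Upstream intergenic gap per gene by a sorted-neighbour walk.

    Valid for non-overlapping sorted genes (the generator's guarantee):
    a plus-strand gene's upstream gap is the space before it, a
    minus-strand gene's the space after it, wrapping across the origin.
    This is the generator's own bookkeeping, independent of the general
    interval-extraction logic it is used to test.
    """
    genes = annotation.genes
    n = len(genes)
    L = annotation.length
    gap_before = {}
    for i, g in enumerate(genes):
        prev = genes[(i - 1) % n]
        gap_before[g.gene_id] = (g.start - prev.end) % L if n > 1 else (
            (g.start - g.end) % L
        )
    out = {}
    for i, g in enumerate(genes):
        if g.strand == "+":
            out[g.gene_id] = gap_before[g.gene_id]
        else:
            nxt = genes[(i + 1) % n]
            out[g.gene_id] = gap_before[nxt.gene_id]
    return out


def plant_truth(annotation: GenomeAnnotation, spec: SyntheticSpec) -> GroundTruth:
    """Choose constitutive and conditional (decoy) genes.

    With ``n_constitutive_short`` set, exactly that many constitutive
    genes are drawn from the short-upstream-gap pool; otherwise the draw
    ignores gap length. Decoys are each assigned a random non-empty
    *strict* subset of samples in which they will be highly expressed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    gaps = upstream_gaps(annotation)
    ids = [g.gene_id for g in annotation.genes]
    if spec.n_constitutive_short is None:
        constitutive = [str(g) for g in rng.choice(ids, size=spec.n_constitutive, replace=False)]
    else:
        short_pool = [g for g in ids if gaps[g] < SHORT_GAP_THRESHOLD]
        long_pool = [g for g in ids if gaps[g] >= SHORT_GAP_THRESHOLD]
        n_short = spec.n_constitutive_short
        n_long = spec.n_constitutive - n_short
        if len(short_pool) < n_short or len(long_pool) < n_long:
            raise ValueError("gap pools too small for requested split")
        constitutive = [
            str(g) for g in rng.choice(short_pool, size=n_short, replace=False)
        ] + [str(g) for g in rng.choice(long_pool, size=n_long, replace=False)]
    remaining = [g for g in ids if g not in set(constitutive)]
    conditional = [
        str(g) for g in rng.choice(remaining, size=spec.n_conditional, replace=False)
    ]
    samples = [f"S{j + 1}" for j in range(spec.n_samples)]
    conditional_samples: dict[str, list[str]] = {}
    for g in conditional:
        if spec.n_samples == 1:
            subset: list[str] = []
        else:
            size = int(rng.integers(1, spec.n_samples))  # strict subset
            subset = sorted(
                (str(x) for x in rng.choice(samples, size=size, replace=False)),
                key=samples.index,
            )
        conditional_samples[g] = subset
    # Best-effort coverage: every sample should carry at least one decoy,
    # so the slot just past the constitutive genes is a known high decoy
    # and never a lottery among background genes.
    covered = {s for sub in conditional_samples.values() for s in sub}
    for s in samples:
        if s in covered:
            continue
        expandable = [
            g for g, sub in conditional_samples.items()
            if len(sub) < spec.n_samples - 1
        ]
        if expandable:
            g = expandable[int(rng.integers(len(expandable)))]
            conditional_samples[g] = sorted(
                conditional_samples[g] + [s], key=samples.index
            )
    short_gap = {
        g for g in constitutive if gaps[g] < SHORT_GAP_THRESHOLD
    }
    return GroundTruth(
        constitutive_ids=set(constitutive),
        conditional_ids=set(conditional),
        short_gap_ids=short_gap,
        conditional_samples=conditional_samples,
        upstream_gap={g: int(v) for g, v in gaps.items()},
    )


# ---------------------------------------------------------------------------
# Count generation


def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2; Poisson
    limit when dispersion = 0."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_counts(
    annotation: GenomeAnnotation,
    spec: SyntheticSpec,
    truth: GroundTruth,
) -> CountMatrix:
    """Genes x samples integer counts with the planted structure.

    Background genes draw from NB(background_mean); constitutive genes
    from NB(high_mean) in every sample; each decoy from
    NB(conditional_mean) only in its assigned sample subset. With
    ``replicates > 1`` each condition gets that many independent columns
    named ``<sample>_rep<i>``.
    """
    ids = [g.gene_id for g in annotation.genes]
    unknown = (truth.constitutive_ids | truth.conditional_ids) - set(ids)
    if unknown:
        raise ValueError(f"truth ids not in annotation: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed + 2)
    samples = [f"S{j + 1}" for j in range(spec.n_samples)]
    columns = {}
    for s in samples:
        for rep in range(spec.replicates):
            col = s if spec.replicates == 1 else f"{s}_rep{rep + 1}"
            means = np.full(len(ids), spec.background_mean)
            for i, g in enumerate(ids):
                if g in truth.constitutive_ids:
                    means[i] = spec.high_mean
                elif g in truth.conditional_ids and s in truth.conditional_samples.get(g, []):
                    means[i] = spec.conditional_mean
            counts = np.array(
                [
                    _nb_draw(rng, m, spec.nb_dispersion, None)
                    for m in means
                ],
                dtype=np.int64,
            )
            columns[col] = counts
    return CountMatrix(pd.DataFrame(columns, index=ids))


# ---------------------------------------------------------------------------
# Assay tables


@dataclass
class TrueAssayParams:
    """Ground-truth parameters the assay tables are built from."""

    promoter_strengths: dict[str, float] = field(
        default_factory=lambda: {"P_A": 250.0, "P_B": 100.0, "P_C": 17.0}
    )
    activities: dict[str, float] = field(
        default_factory=lambda: {"wild_type": 70.0, "engineered": 287.0}
    )
    ammonium_uM: dict[str, float] = field(
        default_factory=lambda: {"wild_type": 14.0, "engineered": 359.1}
    )
    fold_changes: dict[str, float] = field(
        default_factory=lambda: {"nifH": 25.0, "nifA": 127.0}
    )
    reference_luminescence: float = 10_000.0
    blank_luminescence: float = 500.0
    curve_slope: float = 0.002  # absorbance per uM
    curve_intercept: float = 0.05
    protein_mg: float = 0.2
    peak_area_1nmol: float = 1_000.0


@dataclass
class AssayTables:
    """Measurement tables feeding the quantitation formulas."""

    luciferase: pd.DataFrame
    acetylene: pd.DataFrame
    ammonium_standards: pd.DataFrame
    ammonium_samples: pd.DataFrame
    qpcr: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "luciferase",
            "acetylene",
            "ammonium_standards",
            "ammonium_samples",
            "qpcr",
        ):
            p = out_dir / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths


def generate_assay_tables(
    seed: int,
    true_params: TrueAssayParams | None = None,
    noise: float = 0.02,
    n_replicates: int = 3,
) -> AssayTables:
    """Assay tables that the quantitation formulas invert back to
    ``true_params`` up to injected noise.

    ``noise`` is a multiplicative coefficient of variation applied to
    continuous readings (0 gives exact recovery); Ct noise is additive
    with sd ``noise`` cycles. Deterministic per seed.
    """
    tp = true_params or TrueAssayParams()
    rng = np.random.default_rng(seed)

    def jitter(value: float, n: int = 1) -> np.ndarray:
        if noise <= 0:
            return np.full(n, value, dtype=float)
        return value * (1.0 + noise * rng.standard_normal(n))

    # luciferase: strength% -> luminescence above blank, ref = 100%
    rows = []
    groups = {"vector": 0.0, "reference": 100.0, **tp.promoter_strengths}
    span = tp.reference_luminescence - tp.blank_luminescence
    for pid, pct in groups.items():
        lum = tp.blank_luminescence + pct / 100.0 * span
        for i, v in enumerate(jitter(lum, n_replicates)):
            rows.append((f"strain_{pid}", pid, i + 1, max(v, 0.0)))
    luciferase = pd.DataFrame(
        rows, columns=["strain_id", "promoter_id", "replicate", "luminescence"]
    )

    # acetylene reduction: activity -> experimental peak area
    rows = []
    for strain, act in tp.activities.items():
        # invert: act = (peak/std * 100) / (protein * 4)
        peak = act * tp.protein_mg * 4.0 / 100.0 * tp.peak_area_1nmol
        for i, v in enumerate(jitter(peak, n_replicates)):
            rows.append(
                (strain, i + 1, max(v, 0.0), tp.peak_area_1nmol, tp.protein_mg,
                 100.0, 1.0, 4.0)
            )
    acetylene = pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "replicate",
            "peak_area_experimental",
            "peak_area_standard_1nmol",
            "total_protein_mg",
            "headspace_volume_ml",
            "injected_volume_ml",
            "incubation_time_h",
        ],
    )

    # ammonium: standards exact on the true line, samples jittered
    std_conc = np.array([0.0, 50.0, 100.0, 200.0, 400.0])
    std_resp = tp.curve_slope * std_conc + tp.curve_intercept
    if noise > 0:
        std_resp = std_resp * (1.0 + noise * rng.standard_normal(len(std_conc)))
    ammonium_standards = pd.DataFrame(
        {"concentration_uM": std_conc, "absorbance": std_resp}
    )
    rows = []
    for strain, conc in tp.ammonium_uM.items():
        resp = tp.curve_slope * conc + tp.curve_intercept
        for i, v in enumerate(jitter(resp, n_replicates)):
            rows.append((strain, i + 1, v))
    ammonium_samples = pd.DataFrame(
        rows, columns=["strain_id", "replicate", "absorbance"]
    )

    # qPCR: fold -> sample target Ct; calibrator dCt anchored at 5 cycles
    rows = []
    ct_control, ct_cal_target = 20.0, 25.0
    for gene, fold in tp.fold_changes.items():
        ct_sample_target = ct_cal_target - math.log2(fold)
        for i in range(n_replicates):
            dn = noise * rng.standard_normal(4) if noise > 0 else np.zeros(4)
            rows.append(
                ("calibrator", gene, i + 1, ct_cal_target + dn[0], ct_control + dn[1])
            )
            rows.append(
                ("sample", gene, i + 1, ct_sample_target + dn[2], ct_control + dn[3])
            )
    qpcr = pd.DataFrame(
        rows, columns=["strain_id", "gene_id", "replicate", "ct_target", "ct_control"]
    )

    return AssayTables(
        luciferase=luciferase,
        acetylene=acetylene,
        ammonium_standards=ammonium_standards,
        ammonium_samples=ammonium_samples,
        qpcr=qpcr,
    )


# ---------------------------------------------------------------------------
# Bundles


def simulate_bundle(
    spec: SyntheticSpec,
) -> tuple[GenomeAnnotation, CountMatrix, GroundTruth]:
    """Genome + counts + ground truth for one seed."""
    annotation = generate_genome(spec)
    truth = plant_truth(annotation, spec)
    counts = generate_counts(annotation, spec, truth)
    return annotation, counts, truth


def write_bundle(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write genome (GFF3 + FASTA), counts TSV and ground-truth JSON."""
    from .annotation import write_fasta, write_gff3

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation, counts, truth = simulate_bundle(spec)
    paths = {
        "gff3": out_dir / "genome.gff3",
        "fasta": out_dir / "genome.fa",
        "counts": out_dir / "counts.tsv",
        "truth": out_dir / "truth.json",
        "spec": out_dir / "spec.json",
    }
    write_gff3(annotation, paths["gff3"])
    write_fasta(annotation, paths["fasta"])
    counts.to_tsv(paths["counts"])
    truth.to_json(paths["truth"])
    Path(paths["spec"]).write_text(json.dumps(asdict(spec), indent=1))
    return paths
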