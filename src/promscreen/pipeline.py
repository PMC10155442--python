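"""End-to-end orchestration: screen (counts + annotation -> promoters) and
assays (measurement tables -> quantitation reports).

A run is driven by a serializable config so that it is a citable artifact;
reports carry stage counts, all parameters and input checksums, and the
same config on the same inputs produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import read_annotation
from .assays import (
    AcetyleneReductionRecord,
    LuciferaseRecord,
    QPCRRecord,
    fit_standard_curve,
    invert_standard_curve,
    nitrogenase_activity,
    relative_expression,
    relative_strength,
)
from .counts import read_count_table
from .promoters import (
    DEFAULT_MIN_LENGTH,
    export_promoters,
    extract_promoters,
    filter_promoters,
)
from .selection import SelectionParams, intersect_top_sets

logger = logging.getLogger("promscreen")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run (JSON-serializable)."""

    annotation: str | None = None
    annotation_fasta: str | None = None
    counts: str | None = None
    assay_dir: str | None = None
    out_dir: str = "promscreen_out"
    top_fraction: float = 0.03
    min_samples: int | None = None
    aggregation: str = "sum"
    boundary: str = "truncate"
    cpm: bool = False
    min_promoter_length: int = DEFAULT_MIN_LENGTH
    reference_promoter: str = "reference"
    blank_promoter: str = "vector"
    qpcr_calibrator: str = "calibrator"
    circular: bool = True
    seed: int = 0

    def selection_params(self) -> SelectionParams:
        return SelectionParams(
            top_fraction=self.top_fraction,
            min_samples=self.min_samples,
            aggregation=self.aggregation,
            boundary=self.boundary,
            cpm=self.cpm,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_screen(config: PipelineConfig) -> dict:
    """Selection -> extraction -> length filter -> exports.

    Returns the run report (also written to ``out_dir/screen_report.json``)
    with the counts at each stage: number of genes, cutoff size k per
    sample, intersection size, short-region exclusions and retained
    promoters. Intersection members missing from the annotation are
    carried and listed separately, never dropped silently.
    """
    if config.counts is None:
        raise StageError("input", "no counts table configured")
    if config.annotation is None:
        raise StageError("input", "no annotation configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        matrix = read_count_table(config.counts)
    except Exception as e:
        raise StageError("read_counts", str(e)) from e
    if matrix.n_genes == 0:
        raise StageError("read_counts", f"{config.counts}: empty count table")
    try:
        annotation = read_annotation(
            config.annotation,
            fasta=config.annotation_fasta,
            circular=config.circular,
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("read_annotation", str(e)) from e

    logger.info("selection: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    try:
        result = intersect_top_sets(matrix, config.selection_params())
    except Exception as e:
        raise StageError("selection", str(e)) from e

    annotated = sorted(g for g in result.intersection if g in annotation)
    unannotated = sorted(g for g in result.intersection if g not in annotation)
    if unannotated:
        logger.warning(
            "%d intersection genes absent from the annotation: %s",
            len(unannotated),
            unannotated,
        )
    try:
        regions = extract_promoters(annotation, annotated)
        retained, excluded = filter_promoters(
            regions, min_length=config.min_promoter_length
        )
    except Exception as e:
        raise StageError("extraction", str(e)) from e

    result.report().rename_axis("gene_id").to_csv(
        out_dir / "selection_report.tsv", sep="\t"
    )
    result.to_json(out_dir / "per_sample_sets.json")
    export_promoters(
        regions,
        out_dir / "promoters_all",
        replicon_id=annotation.replicon_id,
        fasta=annotation.sequence is not None,
    )
    export_promoters(
        retained,
        out_dir / "promoters_retained",
        replicon_id=annotation.replicon_id,
        fasta=annotation.sequence is not None,
    )

    report = {
        "stage_counts": {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "cutoff_size_per_sample": result.cutoff_size_per_sample,
            "intersection": len(result.intersection),
            "intersection_annotated": len(annotated),
            "n_excluded_short": len(excluded),
            "n_retained": len(retained),
        },
        "unannotated_intersection": unannotated,
        "retained_promoters": sorted(r.promoter_id for r in retained),
        "retained_genes": sorted(r.gene_id for r in retained),
        "excluded_genes": sorted(r.gene_id for r in excluded),
        "params": dataclasses.asdict(config),
        "input_checksums": {
            "counts": _sha256(config.counts),
            "annotation": _sha256(config.annotation),
        },
    }
    (out_dir / "screen_report.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# Assay quantitation runs


def _luciferase_records(df: pd.DataFrame) -> list[LuciferaseRecord]:
    return [
        LuciferaseRecord(
            strain_id=str(r.strain_id),
            promoter_id=str(r.promoter_id),
            replicate_index=int(getattr(r, "replicate", 0)),
            luminescence=float(r.luminescence),
        )
        for r in df.itertuples()
    ]


def run_assays(config: PipelineConfig) -> dict:
    """Quantify every assay table present under ``config.assay_dir``.

    Recognised files: luciferase.tsv, acetylene.tsv,
    ammonium_standards.tsv + ammonium_samples.tsv, qpcr.tsv. Assays with
    no table are skipped with a log line; each computed assay writes a
    TSV next to the combined summary JSON.
    """
    if config.assay_dir is None:
        raise StageError("input", "no assay directory configured")
    assay_dir = Path(config.assay_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"computed": [], "skipped": []}

    def load(name: str) -> pd.DataFrame | None:
        p = assay_dir / f"{name}.tsv"
        if not p.exists():
            logger.info("assay table %s not present; skipped", p.name)
            summary["skipped"].append(name)
            return None
        try:
            return pd.read_csv(p, sep="\t")
        except Exception as e:
            raise StageError("read_assay", f"{p}: {e}") from e

    lux = load("luciferase")
    if lux is not None:
        try:
            strengths = relative_strength(
                _luciferase_records(lux),
                reference_promoter=config.reference_promoter,
                blank=config.blank_promoter,
            )
        except ValueError as e:
            raise StageError("luciferase", str(e)) from e
        df = pd.DataFrame(
            [
                (s.promoter_id, s.percent_of_reference, s.sd_percent, s.n)
                for s in strengths.values()
            ],
            columns=["promoter_id", "percent_of_reference", "sd_percent", "n"],
        ).sort_values("promoter_id")
        df.to_csv(out_dir / "promoter_strengths.tsv", sep="\t", index=False)
        summary["computed"].append("luciferase")
        summary["promoter_strengths"] = {
            s.promoter_id: s.percent_of_reference for s in strengths.values()
        }

    ace = load("acetylene")
    if ace is not None:
        rows = []
        for i, r in enumerate(ace.itertuples()):
            try:
                rec = AcetyleneReductionRecord(
                    strain_id=str(r.strain_id),
                    peak_area_experimental=float(r.peak_area_experimental),
                    peak_area_standard_1nmol=float(r.peak_area_standard_1nmol),
                    total_protein=float(r.total_protein_mg),
                    headspace_volume=float(getattr(r, "headspace_volume_ml", 100.0)),
                    injected_volume=float(getattr(r, "injected_volume_ml", 1.0)),
                    incubation_time=float(getattr(r, "incubation_time_h", 4.0)),
                )
            except (TypeError, ValueError) as e:
                raise StageError("acetylene", f"row {i + 1}: {e}") from e
            rows.append((rec.strain_id, nitrogenase_activity(rec)))
        df = pd.DataFrame(rows, columns=["strain_id", "activity_nmol_h_mg"])
        per_strain = df.groupby("strain_id")["activity_nmol_h_mg"].agg(
            ["mean", "std", "count"]
        )
        per_strain.to_csv(out_dir / "nitrogenase_activity.tsv", sep="\t")
        summary["computed"].append("acetylene")
        summary["nitrogenase_activity"] = per_strain["mean"].to_dict()

    std = load("ammonium_standards")
    smp = load("ammonium_samples")
    if std is not None and smp is not None:
        try:
            curve = fit_standard_curve(
                std["concentration_uM"], std["absorbance"]
            )
        except ValueError as e:
            raise StageError("ammonium", str(e)) from e
        rows = []
        for r in smp.itertuples():
            conc, extrap = invert_standard_curve(curve, float(r.absorbance))
            rows.append((str(r.strain_id), conc, extrap))
        df = pd.DataFrame(
            rows, columns=["strain_id", "ammonium_uM", "extrapolated"]
        )
        per_strain = df.groupby("strain_id")["ammonium_uM"].agg(
            ["mean", "std", "count"]
        )
        per_strain.to_csv(out_dir / "ammonium_concentration.tsv", sep="\t")
        summary["computed"].append("ammonium")
        summary["ammonium_uM"] = per_strain["mean"].to_dict()
        summary["standard_curve"] = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
        }

    qp = load("qpcr")
    if qp is not None:
        cal_name = config.qpcr_calibrator
        rows = []
        for gene, sub in qp.groupby("gene_id"):
            cal = sub[sub["strain_id"] == cal_name]
            if cal.empty:
                raise StageError(
                    "qpcr", f"gene {gene!r}: no calibrator strain {cal_name!r}"
                )
            cal_rec = QPCRRecord(
                strain_id=cal_name,
                gene_id=str(gene),
                ct_target=float(cal["ct_target"].mean()),
                ct_control=float(cal["ct_control"].mean()),
            )
            for strain, ssub in sub[sub["strain_id"] != cal_name].groupby("strain_id"):
                rec = QPCRRecord(
                    strain_id=str(strain),
                    gene_id=str(gene),
                    ct_target=float(ssub["ct_target"].mean()),
                    ct_control=float(ssub["ct_control"].mean()),
                )
                rows.append((str(strain), str(gene), relative_expression(rec, cal_rec)))
        df = pd.DataFrame(rows, columns=["strain_id", "gene_id", "fold_change"])
        df.to_csv(out_dir / "relative_expression.tsv", sep="\t", index=False)
        summary["computed"].append("qpcr")
        summary["fold_changes"] = {
            f"{r.strain_id}:{r.gene_id}": r.fold_change for r in df.itertuples()
        }

    (out_dir / "assay_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
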