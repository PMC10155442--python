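"""Quantitation formulas for the downstream characterisation assays.

Covers: relative promoter strength from luciferase luminescence against a
reference promoter with blank (promoterless-vector) subtraction;
acetylene-reduction nitrogenase activity in nmol ethylene h^-1
(mg protein)^-1; linear standard-curve fitting/inversion for colorimetric
ammonium quantitation; 2^-ddCt relative expression against an internal
control gene; fold-change ratios with half-away-from-zero rounding; and
one-way ANOVA with Tukey HSD pairwise comparisons and significance stars.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class LuciferaseRecord:
    """One luminescence reading at OD600 = 1.0."""

    strain_id: str
    promoter_id: str  # or "vector" (blank) / the reference promoter id
    replicate_index: int
    luminescence: float

    def __post_init__(self) -> None:
        if self.luminescence < 0:
            raise ValueError("luminescence must be >= 0")


@dataclass(frozen=True)
class AcetyleneReductionRecord:
    """Inputs of the acetylene-reduction activity calculation.

    ``peak_area_standard_1nmol`` is the GC detector response for 1 nmol of
    ethylene; ``headspace_volume`` (mL) and ``incubation_time`` (h) default
    to the 100 mL serum bottle and 4 h incubation of the assay.
    ``injected_volume`` (mL) is recorded for provenance but does not enter
    the activity formula.
    """

    strain_id: str
    peak_area_experimental: float
    peak_area_standard_1nmol: float
    total_protein: float  # mg
    headspace_volume: float = 100.0  # mL
    injected_volume: float = 1.0  # mL
    incubation_time: float = 4.0  # h

    def __post_init__(self) -> None:
        if self.peak_area_experimental < 0:
            raise ValueError("experimental peak area must be >= 0")
        for name in ("peak_area_standard_1nmol", "total_protein",
                     "headspace_volume", "incubation_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StandardCurve:
    """A fitted linear response = slope * concentration + intercept."""

    concentrations: list[float]
    responses: list[float]
    slope: float
    intercept: float
    r_squared: float

    @property
    def range(self) -> tuple[float, float]:
        return min(self.concentrations), max(self.concentrations)


@dataclass(frozen=True)
class QPCRRecord:
    """Threshold cycles for a target gene and the internal control gene
    (default internal control: gapdh) in one strain."""

    strain_id: str
    gene_id: str
    ct_target: float
    ct_control: float

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_control):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError("Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_control


# ---------------------------------------------------------------------------
# Luciferase relative strength


@dataclass
class PromoterStrength:
    promoter_id: str
    percent_of_reference: float
    sd_percent: float
    n: int
    clamped: bool = False


def relative_strength(
    records: list[LuciferaseRecord],
    reference_promoter: str,
    blank: str = "vector",
    subtract_blank: bool = True,
) -> dict[str, PromoterStrength]:
    """Promoter strength as percent of a reference promoter.

    strength(p) = 100 * (mean L_p - mean L_blank) / (mean L_ref - mean L_blank)

    Blank subtraction uses the promoterless-vector readings and is on by
    default (``subtract_blank=False`` disables it, in which case the blank
    group, if present, is still reported on the same scale). Negative
    blank-subtracted means are clamped to 0 with a warning. The reported
    sd is the replicate sd of the promoter scaled by the reference
    denominator (ratio-of-means approximation).
    """
    by_promoter: dict[str, list[float]] = {}
    for r in records:
        by_promoter.setdefault(r.promoter_id, []).append(r.luminescence)
    if reference_promoter not in by_promoter:
        raise ValueError(f"reference promoter {reference_promoter!r} has no records")

    blank_mean = 0.0
    if subtract_blank and blank in by_promoter:
        blank_mean = float(np.mean(by_promoter[blank]))
    ref_mean = float(np.mean(by_promoter[reference_promoter]))
    denom = ref_mean - blank_mean
    if denom <= 0:
        raise ValueError(
            "assay invalid: reference signal does not exceed the blank "
            f"({ref_mean} <= {blank_mean})"
        )

    out: dict[str, PromoterStrength] = {}
    for p, values in by_promoter.items():
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        net = mean - blank_mean
        clamped = net < 0
        if clamped:
            warnings.warn(
                f"promoter {p!r}: blank-subtracted signal negative, clamped to 0"
            )
            net = 0.0
        out[p] = PromoterStrength(
            promoter_id=p,
            percent_of_reference=100.0 * net / denom,
            sd_percent=100.0 * sd / denom,
            n=len(values),
            clamped=clamped,
        )
    return out


# ---------------------------------------------------------------------------
# Acetylene reduction (nitrogenase activity)


def nitrogenase_activity(record: AcetyleneReductionRecord) -> float:
    """Nitrogenase activity in nmol ethylene h^-1 (mg protein)^-1.

    activity = (peak_exp / peak_std_1nmol * headspace_mL)
               / (total_protein_mg * incubation_h)

    The peak-area ratio converts detector response to nmol ethylene in the
    injected aliquot; scaling by the headspace volume gives nmol in the
    bottle; protein mass and incubation time normalise to a rate.
    """
    nmol = (
        record.peak_area_experimental / record.peak_area_standard_1nmol
    ) * record.headspace_volume
    return nmol / (record.total_protein * record.incubation_time)


# ---------------------------------------------------------------------------
# Ammonium standard curve


def fit_standard_curve(concentrations, responses) -> StandardCurve:
    """Ordinary least-squares line through (concentration, response) pairs.

    Requires >= 2 distinct concentrations; warns when r^2 < 0.98 (a
    colorimetric standard series should be nearly collinear).
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    fit = stats.linregress(conc, resp)
    if not math.isfinite(fit.slope):
        raise ValueError("standard curve slope is not finite")
    r2 = float(fit.rvalue**2)
    if r2 < 0.98:
        warnings.warn(f"standard curve r^2 = {r2:.4f} < 0.98; check standards")
    return StandardCurve(
        concentrations=list(conc),
        responses=list(resp),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
    )


def invert_standard_curve(
    curve: StandardCurve, response: float
) -> tuple[float, bool]:
    """Concentration for a measured response: (response - intercept)/slope.

    Returns (concentration, extrapolated) where the flag marks values
    outside the fitted standard range.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a zero-slope standard curve")
    conc = (response - curve.intercept) / curve.slope
    lo, hi = curve.range
    return conc, not (lo <= conc <= hi)


# ---------------------------------------------------------------------------
# qPCR relative expression


def relative_expression(sample: QPCRRecord, calibrator: QPCRRecord) -> float:
    """Fold-change by the 2^-ddCt method.

    dCt = Ct(target) - Ct(internal control) per record;
    ddCt = dCt(sample) - dCt(calibrator); fold = 2^-ddCt.
    Amplification efficiency is fixed at 2 (perfect doubling per cycle).
    """
    if sample.gene_id != calibrator.gene_id:
        raise ValueError(
            f"sample gene {sample.gene_id!r} != calibrator gene "
            f"{calibrator.gene_id!r}"
        )
    ddct = sample.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# Fold changes


def fold_change(value_a: float, value_b: float) -> float:
    """Plain ratio value_a / value_b (value_b must be positive)."""
    if value_b <= 0:
        raise ValueError("denominator must be positive")
    return value_a / value_b


def ratio_rounded(value_a: float, value_b: float) -> int:
    """Ratio rounded half away from zero (2.5 -> 3, -2.5 -> -3)."""
    r = fold_change(value_a, value_b)
    return int(math.floor(abs(r) + 0.5) * (1 if r >= 0 else -1))


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Figure-legend star convention: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_adj, stars
    degenerate: bool = False
    groups: list[str] = field(default_factory=list)


def one_way_anova_tukey(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps condition label -> replicate values (>= 2 groups,
    each >= 2 replicates). Pairwise p-values come from the studentized
    range distribution; stars follow the 0.05/0.01/0.001 convention.

    Degenerate input with zero within-group variance everywhere but
    unequal means has no finite F; it is reported with p below the
    machine floor and flagged.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 replicates")

    grand = np.concatenate(arrays).mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)

    degenerate = False
    if ss_within == 0 and ss_between > 0:
        degenerate = True
        f_stat, p_val = math.inf, float(np.nextafter(0, 1))
    elif ss_between == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_val = stats.f_oneway(*arrays)
        f_stat, p_val = float(f_stat), float(p_val)

    rows = []
    if degenerate:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                diff = arrays[j].mean() - arrays[i].mean()
                p = float(np.nextafter(0, 1)) if diff != 0 else 1.0
                rows.append((labels[i], labels[j], diff, p, significance_stars(p, alpha)))
    else:
        tk = stats.tukey_hsd(*arrays)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p = float(tk.pvalue[i, j])
                diff = arrays[j].mean() - arrays[i].mean()
                rows.append((labels[i], labels[j], diff, p, significance_stars(p, alpha)))
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "diff", "p_adj", "stars"]
    )
    return AnovaResult(
        f_statistic=f_stat,
        p_value=p_val,
        pairwise=pairwise,
        degenerate=degenerate,
        groups=labels,
    )
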