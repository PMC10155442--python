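"""Assay quantitation formulas against hand-computed and simulation oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from promscreen import (
    AcetyleneReductionRecord,
    LuciferaseRecord,
    QPCRRecord,
    fit_standard_curve,
    fold_change,
    invert_standard_curve,
    nitrogenase_activity,
    one_way_anova_tukey,
    ratio_rounded,
    relative_expression,
    relative_strength,
    significance_stars,
)


def lux(promoter, *values):
    return [
        LuciferaseRecord("s", promoter, i, v) for i, v in enumerate(values)
    ]


class TestRelativeStrength:
    def test_reference_is_100_percent(self):
        recs = lux("ref", 1000.0) + lux("vector", 0.0) + lux("p", 1000.0)
        out = relative_strength(recs, "ref")
        assert out["p"].percent_of_reference == pytest.approx(100.0)

    def test_blank_subtracted_half(self):
        recs = lux("ref", 1000.0) + lux("vector", 100.0) + lux("p", 550.0)
        out = relative_strength(recs, "ref")
        assert out["p"].percent_of_reference == pytest.approx(50.0)

    def test_promoter_at_blank_is_zero(self):
        recs = lux("ref", 1000.0) + lux("vector", 100.0) + lux("p", 100.0)
        out = relative_strength(recs, "ref")
        assert out["p"].percent_of_reference == 0.0

    def test_below_blank_clamped_with_warning(self):
        recs = lux("ref", 1000.0) + lux("vector", 100.0) + lux("p", 50.0)
        with pytest.warns(UserWarning, match="clamped"):
            out = relative_strength(recs, "ref")
        assert out["p"].percent_of_reference == 0.0
        assert out["p"].clamped

    def test_reference_not_above_blank_invalid(self):
        recs = lux("ref", 90.0) + lux("vector", 100.0)
        with pytest.raises(ValueError, match="reference signal"):
            relative_strength(recs, "ref")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, scale):
        base = lux("ref", 900.0, 1100.0) + lux("vector", 90.0, 110.0) + lux(
            "p", 450.0, 550.0
        )
        scaled = [
            LuciferaseRecord(r.strain_id, r.promoter_id, r.replicate_index,
                             r.luminescence * scale)
            for r in base
        ]
        a = relative_strength(base, "ref")
        b = relative_strength(scaled, "ref")
        for p in a:
            assert a[p].percent_of_reference == pytest.approx(
                b[p].percent_of_reference, rel=1e-9
            )


class TestNitrogenaseActivity:
    def test_unit_case(self):
        rec = AcetyleneReductionRecord(
            "s", peak_area_experimental=500.0, peak_area_standard_1nmol=500.0,
            total_protein=25.0,
        )
        assert nitrogenase_activity(rec) == pytest.approx(1.0)

    def test_zero_peak_zero_activity(self):
        rec = AcetyleneReductionRecord(
            "s", peak_area_experimental=0.0, peak_area_standard_1nmol=500.0,
            total_protein=1.0,
        )
        assert nitrogenase_activity(rec) == 0.0

    def test_hand_arithmetic_287(self):
        # peak ratio 2.296, 0.2 mg protein, 100 mL bottle, 4 h
        rec = AcetyleneReductionRecord(
            "s", peak_area_experimental=2296.0, peak_area_standard_1nmol=1000.0,
            total_protein=0.2,
        )
        assert nitrogenase_activity(rec) == pytest.approx(287.0)

    def test_linearity(self):
        base = AcetyleneReductionRecord(
            "s", peak_area_experimental=300.0, peak_area_standard_1nmol=100.0,
            total_protein=2.0, incubation_time=4.0,
        )
        doubled_peak = AcetyleneReductionRecord(
            "s", peak_area_experimental=600.0, peak_area_standard_1nmol=100.0,
            total_protein=2.0, incubation_time=4.0,
        )
        doubled_protein = AcetyleneReductionRecord(
            "s", peak_area_experimental=300.0, peak_area_standard_1nmol=100.0,
            total_protein=4.0, incubation_time=4.0,
        )
        a = nitrogenase_activity(base)
        assert nitrogenase_activity(doubled_peak) == pytest.approx(2 * a)
        assert nitrogenase_activity(doubled_protein) == pytest.approx(a / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            AcetyleneReductionRecord("s", 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            AcetyleneReductionRecord("s", 1.0, 1.0, 0.0)


class TestStandardCurve:
    def test_two_point_line(self):
        curve = fit_standard_curve([0.0, 100.0], [0.0, 1.0])
        conc, extrap = invert_standard_curve(curve, 0.5)
        assert conc == pytest.approx(50.0)
        assert not extrap

    def test_collinear_r_squared_one(self):
        curve = fit_standard_curve([0, 50, 100, 200], [0.1, 0.6, 1.1, 2.1])
        assert curve.r_squared == pytest.approx(1.0)

    def test_noisy_slope_recovered_vs_closed_form(self):
        rng = np.random.default_rng(3)
        conc = np.array([0.0, 50.0, 100.0, 200.0, 400.0])
        resp = 0.002 * conc + 0.05 + rng.normal(0, 1e-4, size=5)
        curve = fit_standard_curve(conc, resp)
        # closed-form OLS oracle
        x, y = conc, resp
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-12)
        assert curve.slope == pytest.approx(0.002, rel=0.05)

    def test_fit_invert_exact_inverse_on_noiseless(self):
        conc = [0.0, 10.0, 20.0, 40.0]
        curve = fit_standard_curve(conc, [0.05 + 0.01 * c for c in conc])
        for c in (0.0, 5.0, 33.3, 40.0):
            got, _ = invert_standard_curve(curve, 0.05 + 0.01 * c)
            assert got == pytest.approx(c, abs=1e-9)

    def test_extrapolation_flagged(self):
        curve = fit_standard_curve([0.0, 100.0], [0.0, 1.0])
        _, extrap = invert_standard_curve(curve, 2.0)
        assert extrap

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([5.0, 5.0], [0.1, 0.2])

    def test_low_r2_warns(self):
        with pytest.warns(UserWarning, match="r\\^2"):
            fit_standard_curve([0, 1, 2, 3], [0.0, 1.0, 0.0, 1.0])


class TestRelativeExpression:
    def test_identity(self):
        r = QPCRRecord("s", "nifH", 24.0, 20.0)
        assert relative_expression(r, r) == pytest.approx(1.0)

    @pytest.mark.parametrize("ddct,fold", [(-2.0, 4.0), (1.0, 0.5), (0.0, 1.0)])
    def test_closed_form(self, ddct, fold):
        cal = QPCRRecord("cal", "g", 25.0, 20.0)
        smp = QPCRRecord("smp", "g", 25.0 + ddct, 20.0)
        assert relative_expression(smp, cal) == pytest.approx(fold)

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gene"):
            relative_expression(
                QPCRRecord("a", "g1", 20.0, 20.0), QPCRRecord("b", "g2", 20.0, 20.0)
            )

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            QPCRRecord("a", "g", -1.0, 20.0)


class TestFoldChange:
    def test_printed_ratio_rounds_to_18(self):
        assert fold_change(359.1, 20.3) == pytest.approx(17.6896, abs=1e-3)
        assert ratio_rounded(359.1, 20.3) == 18

    def test_identity(self):
        assert fold_change(7.7, 7.7) == pytest.approx(1.0)

    def test_half_away_from_zero(self):
        assert ratio_rounded(10.0, 4.0) == 3  # 2.5 -> 3
        assert ratio_rounded(-10.0, 4.0) == -3

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


def permutation_f_null(groups, rng, n_perm=2000):
    """Permutation oracle: distribution of the one-way F under relabeling."""
    sizes = [len(v) for v in groups]
    pooled = np.concatenate([np.asarray(v, float) for v in groups])

    def f_of(arrs):
        grand = np.concatenate(arrs).mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
        dfb, dfw = len(arrs) - 1, sum(sizes) - len(arrs)
        return (ssb / dfb) / (ssw / dfw)

    fs = []
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        arrs, at = [], 0
        for s in sizes:
            arrs.append(perm[at : at + s])
            at += s
        fs.append(f_of(arrs))
    return np.array(fs), f_of([np.asarray(v, float) for v in groups])


class TestAnova:
    def test_identical_groups_null(self):
        res = one_way_anova_tukey({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_two_far_groups_highly_significant(self):
        res = one_way_anova_tukey({"a": [1.0, 2.0, 3.0], "b": [101.0, 102.0, 103.0]})
        row = res.pairwise.iloc[0]
        assert row.p_adj < 0.001
        assert row.stars == "***"
        # exact permutation null (20 relabelings): the observed F is maximal,
        # so the permutation p equals its attainable floor
        obs = res.f_statistic
        pooled = [1.0, 2.0, 3.0, 101.0, 102.0, 103.0]
        count_ge = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            a = np.array([pooled[i] for i in combo])
            b = np.array([pooled[i] for i in range(6) if i not in combo])
            grand = np.mean(pooled)
            ssb = 3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            f = (ssb / 1) / (ssw / 4)
            total += 1
            count_ge += f >= obs - 1e-9
        assert count_ge / total == pytest.approx(2 / 20)  # the split and its mirror

    def test_manual_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [3.0, 4.0, 5.0]}
        # grand mean 3; SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6; SSW = 2+2+2 = 6
        # F = (6/2)/(6/6) = 3
        res = one_way_anova_tukey(groups)
        assert res.f_statistic == pytest.approx(3.0)
        assert res.p_value == pytest.approx(
            stats.f.sf(3.0, 2, 6), rel=1e-9
        )

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(0, 1, size=6)
            b = rng.normal(0.5, 1, size=9)
            res = one_way_anova_tukey({"a": list(a), "b": list(b)})
            t = stats.ttest_ind(a, b, equal_var=True)
            assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_agrees_with_permutation_oracle_larger_groups(self):
        rng = np.random.default_rng(12)
        groups = {
            "a": list(rng.normal(0.0, 1.0, size=10)),
            "b": list(rng.normal(1.0, 1.0, size=10)),
            "c": list(rng.normal(0.3, 1.0, size=10)),
        }
        res = one_way_anova_tukey(groups)
        fs, obs = permutation_f_null(list(groups.values()), rng, n_perm=4000)
        p_perm = (1 + (fs >= obs).sum()) / (1 + len(fs))
        assert obs == pytest.approx(res.f_statistic, rel=1e-9)
        # permutation and parametric p agree within Monte-Carlo slack
        assert abs(p_perm - res.p_value) < 0.03

    def test_degenerate_zero_within_variance_flagged(self):
        res = one_way_anova_tukey({"a": [5.0, 5.0], "b": [9.0, 9.0]})
        assert res.degenerate
        assert res.p_value < 1e-300
        assert res.pairwise.iloc[0].stars == "***"

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova_tukey({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="replicates"):
            one_way_anova_tukey({"a": [1.0, 2.0], "b": [3.0]})

    def test_tukey_matches_scipy_reference(self):
        rng = np.random.default_rng(4)
        groups = {k: list(rng.normal(m, 1, size=5)) for k, m in
                  zip("abc", (0.0, 1.0, 3.0))}
        res = one_way_anova_tukey(groups)
        ref = stats.tukey_hsd(*[np.array(v) for v in groups.values()])
        for idx, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            assert res.pairwise.iloc[idx].p_adj == pytest.approx(
                float(ref.pvalue[i, j]), rel=1e-9
            )


@pytest.mark.parametrize(
    "p,stars",
    [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***")],
)
def test_significance_stars(p, stars):
    assert significance_stars(p) == stars
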