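import math

import numpy as np
import pandas as pd
import pytest
from oracle_stats import (
    exact_signflip_p,
    rm_anova_permutation_p,
    tukey_maxq_permutation_p,
)

from rpe_granulyzer.audit_rows import CONSISTENT_ROWS
from rpe_granulyzer.classify import FamilyCounts
from rpe_granulyzer.stack_io import ValidationError
from rpe_granulyzer.stats import (
    CellSummary,
    average_size_matches_printed,
    label_richness,
    paired_ttest,
    rm_anova_tukey,
    round_to_printed,
    significance_code,
    summarize_cell,
    tukey_pair_p,
)


class TestPrintedPrecision:
    @pytest.mark.parametrize(
        "count,total,printed",
        [
            (4837, 27.377, "0.006"),  # 27.377/4837 = 0.00566
            (3435, 1.359, "3.96E-04"),  # 1.359/3435 = 3.956e-4
            (11331, 28.355, "0.003"),
            (11263, 7.327, "6.51E-04"),
        ],
    )
    def test_average_size_examples(self, count, total, printed):
        assert average_size_matches_printed(count, total, printed)

    def test_round_to_printed_styles(self):
        assert round_to_printed(0.0056601, "0.006") == "0.006"
        assert round_to_printed(3.956e-4, "3.96E-04") == "3.96E-04"
        assert round_to_printed(0.009569, "0.01") == "0.01"

    def test_reference_rows_identity(self):
        """Every audited published row satisfies size = area / count at its
        printed precision."""
        for table, dose, day, count, total, printed in CONSISTENT_ROWS:
            assert average_size_matches_printed(count, total, printed), (
                table, dose, day, count)


def _summary(count, ratio, cell_id="c", dose="LOW_40", day=1):
    fams = FamilyCounts(
        lipofuscin=10,
        melanolipofuscin=0,
        melanin=int(round(ratio * 10)),
        ratio_incl_ml=ratio,
        ratio_melanin_only=ratio,
    )
    return CellSummary(
        cell_id=cell_id, dose=dose, day=day, count=count,
        total_area_px2=float(count), total_area_um2=count * 0.04,
        average_size_px2=1.0 if count else None, percent_area=10.0,
        mean_intensity=100.0 if count else None, granules_per_um2=0.01,
        families=fams, phenotype_counts={}, cell_area_px2=1000.0,
    )


class TestSummaries:
    def test_summarize_cell_identity(self, default_analysis):
        analysis, _ = default_analysis
        for s in analysis.summaries:
            if s.count:
                assert s.average_size_px2 * s.count == pytest.approx(
                    s.total_area_px2, rel=1e-9
                )
                assert 0 <= s.percent_area <= 100
            else:
                assert s.average_size_px2 is None

    def test_zero_granules_average_missing(self, default_analysis):
        analysis, _ = default_analysis
        geom = analysis.geometries[0]
        s = summarize_cell([], geom)
        assert s.count == 0
        assert s.average_size_px2 is None
        assert s.percent_area == 0.0
        assert s.mean_intensity is None


class TestRichness:
    def _cohort(self):
        return [
            _summary(10, 1.0, "a"), _summary(20, 2.0, "b"), _summary(30, 3.0, "c"),
            _summary(40, 4.0, "d"), _summary(50, 5.0, "e"),
        ]

    def test_cell_at_median_is_rich(self):
        cohort = self._cohort()
        assert label_richness(cohort[2], cohort) == "GRANULE_RICH"

    def test_high_ratio_low_count_is_poor(self):
        cohort = self._cohort()
        poor = _summary(5, 6.0, "p")
        assert label_richness(poor, cohort) == "GRANULE_POOR"

    def test_identical_cohort_all_rich(self):
        cohort = [_summary(10, 1.0, str(i)) for i in range(6)]
        assert all(label_richness(s, cohort) == "GRANULE_RICH" for s in cohort)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            label_richness(_summary(1, 1.0), [_summary(1, 1.0)] * 3)


class TestNucleiCounting:
    def test_planted_counts_recovered(self, default_scene, default_analysis):
        cfg, stack, rois, truth = default_scene
        analysis, _ = default_analysis
        planted = {c.cell_id: c.n_nuclei for c in truth.cells}
        exact = sum(analysis.n_nuclei[c] == planted[c] for c in planted)
        assert exact >= 0.9 * len(planted)

    def test_four_separated_nuclei_and_giant_label(self):
        from rpe_granulyzer.stack_io import CellROI, ZStack
        from rpe_granulyzer.stats import count_nuclei

        rng = np.random.default_rng(0)
        vox = np.zeros((12, 64, 64, 3), dtype=np.uint8)
        vox[..., 2] = np.clip(rng.normal(20, 4, (12, 64, 64)), 0, 255)
        yy, xx = np.mgrid[:64, :64]
        for cx, cy in [(16, 16), (48, 16), (16, 48), (48, 48)]:
            disc = np.hypot(yy - cy, xx - cx) <= 4
            for z in (8, 9, 10):
                vox[z, :, :, 2][disc] = 200
        stack = ZStack(vox, 0.2, 0.5, ("AF488", "TRANS", "NUC"))
        roi = CellROI("c", [(1, 1), (63, 1), (63, 63), (1, 63)], 0, 11)
        n, giant = count_nuclei(stack, roi)
        assert n == 4
        assert giant

    def test_single_nucleus(self):
        from rpe_granulyzer.stack_io import CellROI, ZStack
        from rpe_granulyzer.stats import count_nuclei

        vox = np.zeros((4, 32, 32, 3), dtype=np.uint8)
        vox[..., 2] = 20
        yy, xx = np.mgrid[:32, :32]
        vox[2, :, :, 2][np.hypot(yy - 16, xx - 16) <= 4] = 200
        stack = ZStack(vox, 0.2, 0.5, ("AF488", "TRANS", "NUC"))
        roi = CellROI("c", [(1, 1), (31, 1), (31, 31), (1, 31)], 0, 3)
        n, giant = count_nuclei(stack, roi)
        assert (n, giant) == (1, False)


class TestSignificanceCodes:
    @pytest.mark.parametrize(
        "p,code",
        [(0.5, "ns"), (0.05, "ns"), (0.049, "*"), (0.009, "**"),
         (0.0009, "***"), (0.00009, "****")],
    )
    def test_prism_map(self, p, code):
        assert significance_code(p) == code


def _rm_df(mat, levels=(1, 7, 30)):
    rows = []
    for si, row in enumerate(mat):
        for lv, v in zip(levels, row):
            rows.append({"subject": f"s{si}", "day": lv, "v": v})
    return pd.DataFrame(rows)


class TestRMAnovaTukey:
    def test_identical_groups_null(self):
        mat = np.tile([5.0, 5.0, 5.0], (6, 1))
        res = rm_anova_tukey(_rm_df(mat), "v", "day", "subject")
        assert res.p_value == pytest.approx(1.0)
        assert res.code == "ns"
        assert (res.pairwise["code"] == "ns").all()

    def test_strong_separation_and_permutation_oracle(self):
        rng = np.random.default_rng(42)
        mat = np.column_stack([rng.normal(0, 1, 10), rng.normal(10, 1, 10), rng.normal(0.3, 1, 10)])
        res = rm_anova_tukey(_rm_df(mat), "v", "day", "subject")
        assert res.p_value < 1e-4
        assert tukey_pair_p(res, 1, 7) < 1e-4
        assert res.pairwise.loc[lambda d: (d.level_a == "1") & (d.level_b == "7"), "code"].iloc[0] == "****"
        # far-separated means: permutation oracle agrees the effect is extreme
        assert rm_anova_permutation_p(mat, reps=20_000, seed=1) < 1e-3

    def test_pvalue_matches_within_subject_permutation(self):
        """Parametric RM-ANOVA p agrees with the within-subject permutation
        null on a near-normal mid-p fixture."""
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 1.0, size=(12, 3))
        mat[:, 1] += 0.55
        res = rm_anova_tukey(_rm_df(mat), "v", "day", "subject")
        p_perm = rm_anova_permutation_p(mat, reps=100_000, seed=2)
        assert abs(res.p_value - p_perm) <= 0.02

    def test_tukey_matches_maxq_permutation(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(0, 1.0, size=(12, 3))
        mat[:, 2] += 0.8
        res = rm_anova_tukey(_rm_df(mat), "v", "day", "subject")
        p_param = tukey_pair_p(res, 1, 30)
        p_perm = tukey_maxq_permutation_p(mat, (0, 2), reps=20_000, seed=4)
        assert abs(p_param - p_perm) <= 0.05

    def test_tukey_pair_order_symmetric(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(0, 1, (8, 3))
        res = rm_anova_tukey(_rm_df(mat), "v", "day", "subject")
        assert tukey_pair_p(res, 1, 30) == tukey_pair_p(res, 30, 1)

    def test_unbalanced_falls_back_to_oneway(self):
        df = _rm_df(np.random.default_rng(0).normal(0, 1, (6, 3)))
        df = df[~((df.subject == "s0") & (df.day == 30))]  # break the crossing
        res = rm_anova_tukey(df, "v", "day", "subject")
        assert "fallback" in res.test


class TestPairedTTest:
    def test_identical_series_ns(self):
        res = paired_ttest([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.code == "ns"
        assert res.p_value == 1.0

    def test_strong_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, 10)
        b = a + 1.0 + rng.normal(0, 0.1, 10)
        res = paired_ttest(b, a)
        assert res.p_value < 1e-4
        assert res.code == "****"
        # closed-form t: mean/sd/sqrt(n) on the differences
        d = b - a
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_manual)

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        r1, r2 = paired_ttest(a, b), paired_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_exact_signflip_enumeration(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.45, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        res = paired_ttest(a, b)
        p_exact = exact_signflip_p(a, b)
        assert abs(res.p_value - p_exact) <= 0.02

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_ttest([1.0, 2, 3], [0.0, 1, 2])
        assert res.p_value == 0.0
        assert math.isinf(res.statistic)

    def test_length_validation(self):
        with pytest.raises(ValidationError):
            paired_ttest([1.0], [2.0])
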