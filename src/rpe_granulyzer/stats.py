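"""Per-cell summaries, nuclei counting and the group-level statistics.

Summaries mirror the classic particle-analysis report: Count, Total area,
Average size (= total area / count), % Area (of the cell surface) and Mean.
The "Mean" column is the mean AF intensity of granule pixels (ImageJ
Summarize semantics); a count-flavoured density column is emitted alongside
because the published table captions can be read either way.

Group inference matches the original workflow: repeated-measures one-way
ANOVA with post-hoc Tukey HSD across days (subjects are cells tracked across
synthetic days; a non-repeated design falls back to ordinary one-way ANOVA
with a logged warning), and a paired two-tailed t-test between doses, both at
alpha = 0.05 with Prism-style significance codes (ns, *, **, ***, ****).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .classify import FamilyCounts, family_counts
from .geometry import CellGeometry
from .stack_io import CellROI, ValidationError, ZStack

log = logging.getLogger(__name__)

__all__ = [
    "CellSummary",
    "GroupResult",
    "significance_code",
    "summarize_cell",
    "label_richness",
    "count_nuclei",
    "rm_anova_tukey",
    "paired_ttest",
    "round_to_printed",
    "printed_decimals",
]


# --------------------------------------------------------------------------
# printed-precision helpers (average size is printed to 3 decimals, or 3
# significant figures in scientific notation when below 0.001; other rows
# vary, so comparisons parse the printed string itself)

def printed_decimals(printed: str) -> tuple[int, bool]:
    """(digits, is_scientific) implied by a printed numeric string."""
    s = printed.strip().upper()
    if "E" in s:
        mantissa = s.split("E")[0]
        digits = len(mantissa.replace(".", "").replace("-", "").lstrip("0"))
        return digits, True
    if "." in s:
        return len(s.split(".")[1]), False
    return 0, False


def round_to_printed(value: float, printed: str) -> str:
    """Render ``value`` exactly as the printed string's precision renders it.

    Uses round-half-even (the float formatting default).  Scientific-notation
    strings are matched by significant figures, plain decimals by decimal
    places.
    """
    digits, scientific = printed_decimals(printed)
    if scientific:
        return f"{value:.{max(digits - 1, 0)}E}"
    return f"{value:.{digits}f}"


def average_size_matches_printed(count: float, total_area: float, printed: str) -> bool:
    """Does total_area / count reproduce the printed Average size cell?"""
    recomputed = total_area / count
    target_digits, scientific = printed_decimals(printed)
    rendered = round_to_printed(recomputed, printed)
    return float(rendered) == float(printed)


# --------------------------------------------------------------------------
# per-cell summary

@dataclass
class CellSummary:
    cell_id: str
    dose: str
    day: int
    count: int
    total_area_px2: float
    total_area_um2: float
    average_size_px2: float | None  # None when count == 0, never 0
    percent_area: float
    mean_intensity: float | None  # mean AF of granule pixels
    granules_per_um2: float
    families: FamilyCounts
    phenotype_counts: dict[str, int]
    n_nuclei: int | None = None
    richness: str | None = None
    cell_area_px2: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("count must be >= 0")
        if self.percent_area > 100.0:
            log.warning(
                "cell %s: %%area %.1f > 100 (overlapping granules?)",
                self.cell_id,
                self.percent_area,
            )

    def as_row(self) -> dict:
        f = self.families
        return {
            "cell_id": self.cell_id,
            "dose": self.dose,
            "day": self.day,
            "Count": self.count,
            "Total area": self.total_area_px2,
            "Average size": self.average_size_px2,
            "% Area": self.percent_area,
            "Mean": self.mean_intensity,
            "total_area_um2": self.total_area_um2,
            "granules_per_um2": self.granules_per_um2,
            **{f"n_{p}": self.phenotype_counts.get(p, 0) for p in
               ("L1", "L2", "ML1", "ML2", "M1", "M2")},
            "n_lipofuscin": f.lipofuscin,
            "n_melanolipofuscin": f.melanolipofuscin,
            "n_melanin": f.melanin,
            "melanin_to_lipofuscin_ratio": f.ratio_incl_ml,
            "melanin_only_to_lipofuscin_ratio": f.ratio_melanin_only,
            "n_nuclei": self.n_nuclei,
            "richness": self.richness,
        }


def summarize_cell(
    granules,
    geometry: CellGeometry,
    dose: str = "LOW_40",
    day: int = 1,
    n_nuclei: int | None = None,
) -> CellSummary:
    """Roll classified granules of one cell into the summary-table row."""
    count = len(granules)
    total_area = float(sum(g.area_px2 for g in granules))
    total_um2 = float(sum(g.area_um2 for g in granules))
    if count:
        vox = sum(g.volume_vox for g in granules)
        mean_int = float(sum(g.mean_af * g.volume_vox for g in granules) / vox)
        avg = total_area / count
    else:
        mean_int = None
        avg = None
    pheno: dict[str, int] = {}
    for g in granules:
        if g.label is None:
            raise ValidationError(f"granule {g.granule_id} is unclassified")
        pheno[g.label] = pheno.get(g.label, 0) + 1
    return CellSummary(
        cell_id=geometry.cell_id,
        dose=dose,
        day=day,
        count=count,
        total_area_px2=total_area,
        total_area_um2=total_um2,
        average_size_px2=avg,
        percent_area=100.0 * total_area / geometry.area_px2,
        mean_intensity=mean_int,
        granules_per_um2=count / geometry.area_um2,
        families=family_counts(granules),
        phenotype_counts=pheno,
        n_nuclei=n_nuclei,
        cell_area_px2=geometry.area_px2,
    )


def label_richness(summary: CellSummary, cohort: list[CellSummary]) -> str:
    """GRANULE_POOR iff melanin:lipofuscin ratio above the cohort median AND
    count below the cohort median; GRANULE_RICH otherwise.

    A missing ratio (no lipofuscin and no melanin) falls back to the count
    criterion alone, flagged in the log.
    """
    if len(cohort) < 5:
        raise ValidationError("cohort must contain >= 5 cells")
    ratios = [
        s.families.ratio_incl_ml
        for s in cohort
        if s.families.ratio_incl_ml is not None and math.isfinite(s.families.ratio_incl_ml)
    ]
    med_count = float(np.median([s.count for s in cohort]))
    med_ratio = float(np.median(ratios)) if ratios else float("nan")
    r = summary.families.ratio_incl_ml
    if r is None:
        log.warning("cell %s: ratio undefined, richness from count only", summary.cell_id)
        return "GRANULE_POOR" if summary.count < med_count else "GRANULE_RICH"
    poor = (r > med_ratio) and (summary.count < med_count)
    return "GRANULE_POOR" if poor else "GRANULE_RICH"


def count_nuclei(
    stack: ZStack,
    roi: CellROI,
    channel: str = "NUC",
    min_nucleus_area_px2: float = 12.0,
    giant_min_nuclei: int = 3,
) -> tuple[int, bool]:
    """Count nuclei of one cell; returns (n_nuclei, is_multinucleated_giant).

    Max-projects the nuclei channel over z inside the cell mask, thresholds
    by Otsu (clamped above the background), fills holes and counts connected
    components of at least ``min_nucleus_area_px2``.
    """
    from skimage.filters import gaussian, threshold_otsu

    if not stack.has_channel(channel):
        log.warning("no %r channel: skipping nuclei counting", channel)
        return 0, False
    mask = roi.raster_mask(stack.shape_yx)
    ys, xs = np.nonzero(mask)
    y0, y1, x0, x1 = ys.min(), ys.max(), xs.min(), xs.max()
    mask = mask[y0 : y1 + 1, x0 : x1 + 1]
    proj = stack.channel(channel)[:, y0 : y1 + 1, x0 : x1 + 1].max(axis=0).astype(np.float64)
    proj = gaussian(proj, 1.0, preserve_range=True)
    vals = proj[mask]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med))) * 1.4826
    if np.ptp(vals) == 0:
        return 0, False
    t = max(float(threshold_otsu(vals)), med + 3.0 * max(mad, 1e-6))
    binary = (proj > t) & mask
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        n = int((sizes >= min_nucleus_area_px2).sum())
    return n, n >= giant_min_nuclei


# --------------------------------------------------------------------------
# group statistics

SIGNIFICANCE_CODES = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_code(p: float) -> str:
    """Prism-style code: **** < 0.0001 < *** < 0.001 < ** < 0.01 < * < 0.05 <= ns."""
    for cut, code in SIGNIFICANCE_CODES:
        if p < cut:
            return code
    return "ns"


@dataclass
class GroupResult:
    test: str
    statistic: float
    p_value: float
    code: str
    levels: tuple = ()
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.code != significance_code(self.p_value):
            raise ValidationError("significance code inconsistent with p-value")


def rm_anova_tukey(df: pd.DataFrame, value: str, level: str, subject: str) -> GroupResult:
    """Repeated-measures one-way ANOVA with post-hoc Tukey HSD.

    ``df`` holds one row per (subject, level) observation.  When subjects are
    not fully crossed with levels the design is not repeated-measures and the
    function falls back to an ordinary one-way ANOVA with a logged warning.
    Tukey is computed on the level groups either way; the pairwise table has
    columns (level_a, level_b, meandiff, p_adj, code).
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    levels = tuple(sorted(df[level].unique()))
    if len(levels) < 2:
        raise ValidationError("need >= 2 levels")
    counts = df.groupby(level)[subject].nunique()
    if (counts < 2).any():
        raise ValidationError("need >= 2 subjects per level")

    pivot = df.pivot_table(index=subject, columns=level, values=value, aggfunc="mean")
    balanced = not pivot.isna().any().any()
    groups = [df.loc[df[level] == lv, value].to_numpy(float) for lv in levels]
    if balanced:
        try:
            res = AnovaRM(
                df.groupby([subject, level], as_index=False)[value].mean(),
                depvar=value,
                subject=subject,
                within=[level],
            ).fit()
            f = float(res.anova_table["F Value"].iloc[0])
            p = float(res.anova_table["Pr > F"].iloc[0])
            test = "RM one-way ANOVA"
        except Exception:  # degenerate (e.g. zero within-variance)
            f, p, test = 0.0, 1.0, "RM one-way ANOVA (degenerate)"
        # post-hoc Tukey with the repeated-measures error term: q against the
        # studentized range with df = (n-1)(k-1), as Prism does for RM designs
        mat = pivot[list(levels)].to_numpy(float)
        n, k = mat.shape
        grand = mat.mean()
        resid = mat - mat.mean(axis=0) - mat.mean(axis=1, keepdims=True) + grand
        df_err = (n - 1) * (k - 1)
        ms_err = float((resid**2).sum()) / df_err
        se = math.sqrt(ms_err / n) if ms_err > 0 else 0.0
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(mat[:, j].mean() - mat[:, i].mean())
                if se > 0:
                    q = abs(diff) / se
                    p_adj = float(sps.studentized_range.sf(q, k, df_err))
                else:
                    p_adj = 1.0 if diff == 0 else 0.0
                rows.append((str(levels[i]), str(levels[j]), diff, min(max(p_adj, 0.0), 1.0)))
        pairwise = pd.DataFrame(rows, columns=["level_a", "level_b", "meandiff", "p_adj"])
    else:
        log.warning("subjects not crossed with levels: ordinary one-way ANOVA fallback")
        f, p = sps.f_oneway(*groups)
        f = float(f) if np.isfinite(f) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
        test = "one-way ANOVA (fallback)"
        tk = pairwise_tukeyhsd(
            df[value].to_numpy(float), df[level].astype(str).to_numpy()
        )
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        pairwise = pd.DataFrame(
            {
                "level_a": frame["group1"],
                "level_b": frame["group2"],
                "meandiff": frame["meandiff"].astype(float),
                "p_adj": np.asarray(tk.pvalues, dtype=float),
            }
        )
    if not np.isfinite(p):  # identical groups
        f, p = 0.0, 1.0
    pairwise["code"] = [significance_code(p_) for p_ in pairwise["p_adj"]]
    return GroupResult(
        test=test,
        statistic=f,
        p_value=min(max(p, 0.0), 1.0),
        code=significance_code(p),
        levels=levels,
        pairwise=pairwise,
    )


def tukey_pair_p(result: GroupResult, a, b) -> float:
    """Adjusted p for one level pair from a GroupResult (order-insensitive)."""
    pw = result.pairwise
    sel = ((pw.level_a == str(a)) & (pw.level_b == str(b))) | (
        (pw.level_a == str(b)) & (pw.level_b == str(a))
    )
    if not sel.any():
        raise KeyError((a, b))
    return float(pw.loc[sel, "p_adj"].iloc[0])


def paired_ttest(series_a, series_b) -> GroupResult:
    """Two-tailed paired t-test (pairs by position).

    Zero-variance differences are handled explicitly: all-zero differences
    give t = 0, p = 1; a constant non-zero difference is reported as p = 0
    (the parametric statistic diverges).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("series must be equal-length 1-D with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, d.mean())
            p = 0.0
    else:
        t, p = sps.ttest_rel(a, b)
        t, p = float(t), float(p)
    return GroupResult(
        test="paired two-tailed t-test",
        statistic=t,
        p_value=min(max(p, 0.0), 1.0),
        code=significance_code(p),
        levels=("a", "b"),
    )
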