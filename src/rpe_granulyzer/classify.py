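"""Six-phenotype granule classification and family roll-ups.

Each detected granule is assigned one of L1 / L2 / ML1 / ML2 / M1 / M2 from
its autofluorescence pattern and shape, via a first-match decision list so
that every assignment carries an auditable rationale:

  R1  bull's-eye: bright ring around a dark core, mid-or-higher AF  -> ML2
  R2  dark (no 488 nm excitation) and spindle-shaped                -> M2
  R3  dark and round                                                -> M1
  R4  bright and irregular or large aggregate                       -> L2
  R5  bright and round monolithic granule                           -> L1
  R6  intermediate AF, large and round                              -> ML1
  R7  fallback: nearest rule in normalised feature space

The AF thresholds are background-relative z-scores and the remaining numeric
cut-offs are declared fixtures (the visual classification this reproduces
published no numbers); all are configurable.  Intermediate melanosome-to-
lipofuscin conversion states have no seventh label: they land in ML1 or the
fallback, flagged in the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .detect import Granule
from .stack_io import ValidationError
from .synthetic import FAMILY_OF, PHENOTYPES

__all__ = [
    "ClassifyParams",
    "PhenotypeLabel",
    "classify",
    "classify_all",
    "family_counts",
    "FamilyCounts",
]


@dataclass
class ClassifyParams:
    """Thresholds for the decision list.

    AF levels are absolute intensities derived from the image background b
    and noise sd: lo/mid/hi = b + (2, 5, 8) * sd; ring threshold 3 * sd.
    ``area_big_px2`` marks "large" granules and defaults to the cohort's
    90th-percentile granule area (set it with :meth:`with_cohort`).
    """

    t_af_lo: float = 46.0
    t_af_mid: float = 70.0
    t_af_hi: float = 94.0
    t_ring: float = 24.0
    area_big_px2: float = 40.0
    circ_irregular: float = 0.6
    circ_large_round: float = 0.7
    circ_round: float = 0.8
    aspect_spindle: float = 2.0

    @classmethod
    def from_background(cls, background: float, noise_sd: float, **kw) -> "ClassifyParams":
        return cls(
            t_af_lo=background + 2.0 * noise_sd,
            t_af_mid=background + 5.0 * noise_sd,
            t_af_hi=background + 8.0 * noise_sd,
            t_ring=3.0 * noise_sd,
            **kw,
        )

    def with_cohort(self, granules: Sequence[Granule]) -> "ClassifyParams":
        """Return a copy with area_big set to the cohort's 90th percentile."""
        from dataclasses import replace

        if not granules:
            return self
        areas = np.array([g.area_px2 for g in granules])
        return replace(self, area_big_px2=float(np.percentile(areas, 90)))


@dataclass
class PhenotypeLabel:
    label: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype {self.label!r}")
        if not self.rationale:
            raise ValidationError("rationale must be non-empty")

    @property
    def family(self) -> str:
        return FAMILY_OF[self.label]


def _rule_conditions(g: Granule, p: ClassifyParams) -> list[tuple[str, str, bool]]:
    """(rule id, label, fired) in decision-list order."""
    return [
        ("R1", "ML2", g.ring_score >= p.t_ring and g.mean_af >= p.t_af_mid),
        ("R2", "M2", g.mean_af < p.t_af_lo and g.aspect_ratio >= p.aspect_spindle),
        ("R3", "M1", g.mean_af < p.t_af_lo and g.circularity >= p.circ_round),
        (
            "R4",
            "L2",
            g.mean_af >= p.t_af_hi
            and (g.circularity < p.circ_irregular or g.area_px2 > p.area_big_px2),
        ),
        ("R5", "L1", g.mean_af >= p.t_af_hi and g.circularity >= p.circ_round),
        (
            "R6",
            "ML1",
            p.t_af_lo <= g.mean_af < p.t_af_hi
            and g.circularity >= p.circ_large_round
            and g.area_px2 >= p.area_big_px2,
        ),
    ]


def _fallback(g: Granule, p: ClassifyParams) -> str:
    """Nearest rule by normalised feature distance.

    Each rule is represented by a prototype in (AF z-score, circularity,
    aspect, ring z-score, log-area) space; scales make one threshold width
    one distance unit.
    """
    sd = max((p.t_af_mid - p.t_af_lo) / 3.0, 1e-6)  # noise sd implied by thresholds
    b = p.t_af_lo - 2.0 * sd
    feats = np.array(
        [
            (g.mean_af - b) / sd,
            g.circularity,
            min(g.aspect_ratio, 6.0),
            g.ring_score / sd,
            np.log(max(g.area_px2, 1.0) / p.area_big_px2),
        ]
    )
    protos = {
        "ML2": (5.5, 0.85, 1.2, 6.0, 0.0),
        "M2": (0.0, 0.5, 3.0, 0.0, -0.5),
        "M1": (0.0, 0.9, 1.1, 0.0, -0.7),
        "L2": (9.0, 0.5, 1.5, 0.0, 0.2),
        "L1": (9.0, 0.9, 1.1, 0.0, -0.7),
        "ML1": (4.0, 0.9, 1.1, 0.0, 0.3),
    }
    scales = np.array([2.0, 0.15, 1.0, 3.0, 0.7])
    best, best_d = None, np.inf
    for label, proto in protos.items():
        d = float(np.sum(((feats - np.asarray(proto)) / scales) ** 2))
        if d < best_d:
            best, best_d = label, d
    return best


def classify(granule: Granule, params: ClassifyParams | None = None) -> PhenotypeLabel:
    """Assign a phenotype via the first-match decision list (pure function)."""
    p = params or ClassifyParams()
    rationale: list[str] = []
    for rule_id, label, fired in _rule_conditions(granule, p):
        if fired:
            rationale.append(rule_id)
            return PhenotypeLabel(label=label, rationale=tuple(rationale))
    label = _fallback(granule, p)
    return PhenotypeLabel(label=label, rationale=("fallback",))


def classify_all(
    granules: Sequence[Granule], params: ClassifyParams | None = None
) -> list[Granule]:
    """Classify a cohort in place; area_big defaults to the cohort 90th pct."""
    p = (params or ClassifyParams()).with_cohort(granules) if params is None else params
    for g in granules:
        lab = classify(g, p)
        g.label = lab.label
        g.family = lab.family
        g.rationale = lab.rationale
    return list(granules)


@dataclass
class FamilyCounts:
    lipofuscin: int
    melanolipofuscin: int
    melanin: int
    #: (melanin + melanolipofuscin) / lipofuscin — the published "melanin +
    #: melanosome to lipofuscin" reading; inf when the denominator alone is 0
    ratio_incl_ml: float | None
    #: pure melanin / lipofuscin — the conservative alternative reading
    ratio_melanin_only: float | None


def _ratio(num: int, den: int) -> float | None:
    if den == 0:
        return float("inf") if num > 0 else None
    return num / den


def family_counts(granules: Iterable[Granule]) -> FamilyCounts:
    """Counts per family plus both melanin-to-lipofuscin ratio variants."""
    counts = {"LIPOFUSCIN": 0, "MELANOLIPOFUSCIN": 0, "MELANIN": 0}
    for g in granules:
        if g.family is None:
            raise ValidationError(f"granule {g.granule_id} is unclassified")
        counts[g.family] += 1
    lip = counts["LIPOFUSCIN"]
    ml = counts["MELANOLIPOFUSCIN"]
    mel = counts["MELANIN"]
    return FamilyCounts(
        lipofuscin=lip,
        melanolipofuscin=ml,
        melanin=mel,
        ratio_incl_ml=_ratio(mel + ml, lip),
        ratio_melanin_only=_ratio(mel, lip),
    )
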