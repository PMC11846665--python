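"""Composite radiographic knee osteoarthritis (rKOA) scoring.

The classifier mirrors the Kellgren–Lawrence idea with quantitative inputs:

* medial joint-space-narrowing (JSN) grade 0–3 from mJSW thresholds
  (>3 mm → 0; >2.5–≤3 → 1; >2–≤2.5 → 2; <2 → 3);
* four osteophyte grades 0–3, summed and weighted by 0.5 (max 6);
* sum score = 0.5·Σ(osteophyte grades) + JSN grade, range 0–9;
* rKOA grade from the sum score: 0 at 0; 1 in (0, 1.5]; 2 in (1.5, 3];
  3 in (3, 4.5]; 4 above 4.5. Grades 3 and 4 are additionally collapsed
  to a single "3–4" category for association analyses.

An mJSW of exactly 2 mm sits between the printed ">2" and "<2" bands; it is
assigned the more severe grade 3 by default (``cfg.jsn_boundary_grade``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import SITES, GraderConfig, Site
from .geometry import height_normalize, mjsw
from .io import LandmarkSet, SiteAnnotation
from .osteophytes import OsteophyteGradeSet, grade_all_sites

MAX_SUM_SCORE = 9.0


@dataclass(frozen=True)
class GradeRecord:
    """Full per-scan grading output of the classifier."""

    subject_id: str
    side: str
    areas_mm2: dict[Site, float]
    osteophyte_grades: dict[Site, int]
    medial_mjsw_mm: float
    lateral_mjsw_mm: float
    medial_mjsw_norm_mm: Optional[float]
    jsn_grade: int
    lateral_jsn_grade: int  # reported only; never enters the sum score
    sum_score: float
    rkoa_grade: int
    rkoa_grade_collapsed: int

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "side": self.side}
        for site in SITES:
            row[f"area_{site.value}_mm2"] = self.areas_mm2[site]
            row[f"op_grade_{site.value}"] = self.osteophyte_grades[site]
        row.update(
            medial_mjsw_mm=self.medial_mjsw_mm,
            lateral_mjsw_mm=self.lateral_mjsw_mm,
            medial_mjsw_norm_mm=self.medial_mjsw_norm_mm,
            jsn_grade=self.jsn_grade,
            lateral_jsn_grade=self.lateral_jsn_grade,
            sum_score=self.sum_score,
            rkoa_grade=self.rkoa_grade,
            rkoa_grade_collapsed=self.rkoa_grade_collapsed,
        )
        return row


def jsn_grade_from_mjsw(mjsw_mm: float, cfg: GraderConfig) -> int:
    """Medial JSN grade 0–3 from a measured mJSW in mm."""
    if mjsw_mm < 0:
        raise ValueError(f"negative mJSW {mjsw_mm}")
    t0, t1, t2 = cfg.jsn_thresholds_mm
    if mjsw_mm > t0:
        return 0
    if mjsw_mm > t1:
        return 1
    if mjsw_mm > t2:
        return 2
    if mjsw_mm < t2:
        return 3
    return cfg.jsn_boundary_grade  # exactly at the lowest cut


def sum_score(op: OsteophyteGradeSet, jsn: int, cfg: GraderConfig) -> float:
    """Weighted composite score: weight·Σ(osteophyte grades) + JSN grade."""
    if jsn not in (0, 1, 2, 3):
        raise ValueError(f"JSN grade {jsn} outside 0–3")
    score = cfg.osteophyte_weight * op.total + jsn
    if not (0 <= score <= MAX_SUM_SCORE) and cfg.osteophyte_weight == 0.5:
        raise ValueError(f"sum score {score} outside [0, {MAX_SUM_SCORE}]")
    return float(score)


def rkoa_grade_from_score(score: float, cfg: GraderConfig) -> int:
    """Bin a composite sum score into the overall 0–4 rKOA grade."""
    c0, c1, c2, c3 = cfg.rkoa_cuts
    if not (0 <= score <= MAX_SUM_SCORE):
        raise ValueError(f"sum score {score} outside [0, {MAX_SUM_SCORE}]")
    if score == c0:
        return 0
    if score <= c1:
        return 1
    if score <= c2:
        return 2
    if score <= c3:
        return 3
    return 4


def collapse_rkoa(grade: int) -> int:
    """Collapse rKOA grades 3 and 4 into one '3–4' category (coded 3)."""
    if grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"rKOA grade {grade} outside 0–4")
    return min(grade, 3)


def rkoa_grade_from_score_array(scores: np.ndarray, cfg: GraderConfig) -> np.ndarray:
    """Vectorised counterpart of :func:`rkoa_grade_from_score`."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > MAX_SUM_SCORE)):
        raise ValueError("sum scores outside [0, 9]")
    c0, c1, c2, c3 = cfg.rkoa_cuts
    return np.select(
        [s == c0, s <= c1, s <= c2, s <= c3], [0, 1, 2, 3], default=4
    ).astype(int)


def grade_scan(
    lm: LandmarkSet,
    annotations: list[SiteAnnotation],
    cfg: GraderConfig,
    *,
    height_cm: Optional[float] = None,
    mean_height_cm: Optional[float] = None,
) -> GradeRecord:
    """Run the full classifier on one scan.

    Measures medial/lateral mJSW from the landmarks, grades the osteophyte
    annotations, assigns the medial JSN grade (from the height-normalised
    mJSW when both heights are given), and composes the sum score and rKOA
    grade. The lateral JSN grade is computed for reporting but never enters
    the composite — the classifier is medial-only by design.
    """
    measure = mjsw(lm, cfg)
    op = grade_all_sites(annotations, cfg)

    med = measure.medial_mjsw_mm
    norm: Optional[float] = None
    if height_cm is not None and mean_height_cm is not None:
        norm = height_normalize(med, height_cm, mean_height_cm, cfg.height_norm_mode)
    jsn = jsn_grade_from_mjsw(norm if norm is not None else med, cfg)
    lat_jsn = jsn_grade_from_mjsw(measure.lateral_mjsw_mm, cfg)

    score = sum_score(op, jsn, cfg)
    grade = rkoa_grade_from_score(score, cfg)
    return GradeRecord(
        subject_id=lm.subject_id,
        side=lm.side.value,
        areas_mm2=op.areas_mm2,
        osteophyte_grades=op.grades,
        medial_mjsw_mm=med,
        lateral_mjsw_mm=measure.lateral_mjsw_mm,
        medial_mjsw_norm_mm=norm,
        jsn_grade=jsn,
        lateral_jsn_grade=lat_jsn,
        sum_score=score,
        rkoa_grade=grade,
        rkoa_grade_collapsed=collapse_rkoa(grade),
    )
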