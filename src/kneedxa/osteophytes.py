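"""Osteophyte area measurement and 0–3 grading.

An osteophyte annotation is either a shaded binary mask (area = pixel count
× spacing²) or a precomputed area in mm². Grades follow an absence rule plus
two configurable area cut points: grade 0 iff no osteophyte (area 0), grade
1 for (0, t1], grade 2 for (t1, t2], grade 3 above t2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import SITES, GraderConfig, Site
from .io import SiteAnnotation


@dataclass(frozen=True)
class OsteophyteGradeSet:
    """Per-site osteophyte areas (mm²) and grades (0–3) for one scan."""

    areas_mm2: dict[Site, float]
    grades: dict[Site, int]

    def __post_init__(self) -> None:
        for site in SITES:
            g, a = self.grades[site], self.areas_mm2[site]
            if g not in (0, 1, 2, 3):
                raise ValueError(f"{site.value}: grade {g} outside 0–3")
            if (g == 0) != (a == 0.0):
                raise ValueError(
                    f"{site.value}: grade 0 must coincide with area 0 (grade {g}, area {a})"
                )

    @property
    def total(self) -> int:
        """Unweighted sum of the four grades (0–12)."""
        return sum(self.grades.values())


def mask_area_mm2(ann: SiteAnnotation) -> float:
    """Osteophyte area in mm²: precomputed value, or pixel count × spacing²."""
    if ann.area_mm2 is not None:
        return float(ann.area_mm2)
    if ann.pixel_spacing_mm is None:
        raise ValueError("mask annotation without pixel spacing")
    return float(np.count_nonzero(ann.mask)) * ann.pixel_spacing_mm**2


def grade_osteophyte(area_mm2: float, cfg: GraderConfig) -> int:
    """Grade one site's osteophyte area on the 0–3 scale."""
    if area_mm2 < 0:
        raise ValueError(f"negative osteophyte area {area_mm2}")
    t1, t2 = cfg.osteophyte_area_thresholds_mm2
    if area_mm2 == 0:
        return 0
    if area_mm2 <= t1:
        return 1
    if area_mm2 <= t2:
        return 2
    return 3


def grade_all_sites(
    annotations: Sequence[SiteAnnotation], cfg: GraderConfig
) -> OsteophyteGradeSet:
    """Grade every site; unannotated sites score area 0, grade 0."""
    areas = {site: 0.0 for site in SITES}
    seen: set[Site] = set()
    for ann in annotations:
        if ann.site in seen:
            raise ValueError(f"duplicate annotation for site {ann.site.value}")
        seen.add(ann.site)
        areas[ann.site] = mask_area_mm2(ann)
    grades = {site: grade_osteophyte(areas[site], cfg) for site in SITES}
    return OsteophyteGradeSet(areas_mm2=areas, grades=grades)
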