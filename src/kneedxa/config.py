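"""Grader configuration: landmark subsets, grading thresholds and I/O conventions.

All thresholds that define the classifier live here so that every cut point
(joint-space-narrowing bands, osteophyte area bands, composite-grade bins)
is explicit, serialisable to YAML, and validated on construction.

Landmark index ranges are written 1-based inclusive, the convention used when
the 129-point knee annotation scheme is described; they are converted to
0-based slices internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Union

import yaml

N_LANDMARKS = 129


class Side(str, Enum):
    RIGHT = "right"
    LEFT = "left"


class Site(str, Enum):
    """The four osteophyte sites assessed at the tibiofemoral joint margins."""

    MEDIAL_FEMUR = "medial_femur"
    LATERAL_FEMUR = "lateral_femur"
    MEDIAL_TIBIA = "medial_tibia"
    LATERAL_TIBIA = "lateral_tibia"


SITES = tuple(Site)


class ConfigError(ValueError):
    """Raised when a GraderConfig violates its invariants."""


#: Default raster colours for shaded osteophyte masks, one per site.
DEFAULT_MASK_COLORS: dict[Site, tuple[int, int, int]] = {
    Site.MEDIAL_FEMUR: (255, 0, 0),     # red
    Site.LATERAL_FEMUR: (0, 255, 0),    # green
    Site.MEDIAL_TIBIA: (255, 255, 0),   # yellow
    Site.LATERAL_TIBIA: (0, 0, 255),    # blue
}


@dataclass(frozen=True)
class GraderConfig:
    """Thresholds and conventions of the composite rKOA classifier.

    Parameters
    ----------
    femur_medial_idx, femur_lateral_idx, tibia_medial_idx, tibia_lateral_idx
        1-based inclusive landmark index ranges delimiting the joint-surface
        subsets between which minimum joint space width is measured.
    osteophyte_area_thresholds_mm2
        Two increasing cut points ``(t1, t2)`` in mm². Osteophyte grade is 0
        iff the area is 0, 1 for area in (0, t1], 2 for (t1, t2], 3 above t2.
        The defaults (10, 25) are placeholders motivated by the published
        per-site mean areas (11.6–26.9 mm²); they are NOT the calibrated
        supplementary cut points, which are not in the public text.
    jsn_thresholds_mm
        Strictly decreasing mJSW cut points ``(3.0, 2.5, 2.0)`` mm: grade 0
        above the first, then bands (2.5, 3], (2, 2.5], grade 3 below 2 mm.
    jsn_boundary_grade
        Grade assigned at exactly 2.0 mm, which the printed intervals leave
        unassigned. Default 3 (the more severe reading).
    rkoa_cuts
        Composite-score bin edges ``(0, 1.5, 3, 4.5)``: grade 0 only at score
        0, then left-open/right-closed bins, grade 4 above 4.5.
    osteophyte_weight
        Weight applied to the summed osteophyte grades (default 0.5, giving a
        maximum osteophyte contribution of 6 and maximum sum score of 9).
    distance_mode
        ``"segment"`` (bidirectional point-to-segment minimum, default) or
        ``"point"`` (closest landmark pair only).
    height_norm_mode
        ``"scale_to_mean"`` — mJSW × mean_height/height — or
        ``"divide_by_height"``.
    """

    femur_medial_idx: tuple[int, int] = (24, 30)
    femur_lateral_idx: tuple[int, int] = (15, 20)
    tibia_medial_idx: tuple[int, int] = (68, 73)
    tibia_lateral_idx: tuple[int, int] = (57, 62)
    osteophyte_area_thresholds_mm2: tuple[float, float] = (10.0, 25.0)
    jsn_thresholds_mm: tuple[float, float, float] = (3.0, 2.5, 2.0)
    jsn_boundary_grade: int = 3
    rkoa_cuts: tuple[float, float, float, float] = (0.0, 1.5, 3.0, 4.5)
    osteophyte_weight: float = 0.5
    distance_mode: str = "segment"
    height_norm_mode: str = "scale_to_mean"
    mask_color_map: dict[Site, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_MASK_COLORS)
    )

    def __post_init__(self) -> None:
        ranges = {
            "femur_medial_idx": self.femur_medial_idx,
            "femur_lateral_idx": self.femur_lateral_idx,
            "tibia_medial_idx": self.tibia_medial_idx,
            "tibia_lateral_idx": self.tibia_lateral_idx,
        }
        covered: set[int] = set()
        for name, (lo, hi) in ranges.items():
            if not (1 <= lo <= hi <= N_LANDMARKS):
                raise ConfigError(
                    f"{name}={lo}-{hi} outside the valid 1..{N_LANDMARKS} range"
                )
            span = set(range(lo, hi + 1))
            if covered & span:
                raise ConfigError(f"{name}={lo}-{hi} overlaps another subset range")
            covered |= span

        t1, t2 = self.osteophyte_area_thresholds_mm2
        if not (0 < t1 < t2):
            raise ConfigError(
                "osteophyte_area_thresholds_mm2 must be strictly increasing and positive, "
                f"got {self.osteophyte_area_thresholds_mm2}"
            )
        j = self.jsn_thresholds_mm
        if not (j[0] > j[1] > j[2] > 0):
            raise ConfigError(
                f"jsn_thresholds_mm must be strictly decreasing and positive, got {j}"
            )
        c = self.rkoa_cuts
        if not (c[0] == 0 and c[0] < c[1] < c[2] < c[3]):
            raise ConfigError(
                f"rkoa_cuts must start at 0 and strictly increase, got {c}"
            )
        if self.jsn_boundary_grade not in (2, 3):
            raise ConfigError("jsn_boundary_grade must be 2 or 3")
        if self.osteophyte_weight <= 0:
            raise ConfigError("osteophyte_weight must be positive")
        if self.distance_mode not in ("segment", "point"):
            raise ConfigError("distance_mode must be 'segment' or 'point'")
        if self.height_norm_mode not in ("scale_to_mean", "divide_by_height"):
            raise ConfigError(
                "height_norm_mode must be 'scale_to_mean' or 'divide_by_height'"
            )
        if set(self.mask_color_map) != set(SITES):
            raise ConfigError("mask_color_map must map all four sites")
        seen_colors = list(self.mask_color_map.values())
        if len(set(map(tuple, seen_colors))) != len(seen_colors):
            raise ConfigError("mask_color_map colours must be distinct")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mask_color_map"] = {
            site.value: list(rgb) for site, rgb in self.mask_color_map.items()
        }
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GraderConfig":
        defaults = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name == "mask_color_map":
                v = {Site(k): tuple(rgb) for k, rgb in v.items()}
            elif isinstance(getattr(defaults, f.name), tuple):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)


def read_config(path: Union[str, Path]) -> GraderConfig:
    """Load a GraderConfig from YAML; absent keys take their defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} is not a YAML mapping")
    return GraderConfig.from_dict(doc)


def write_config(cfg: GraderConfig, path: Union[str, Path]) -> None:
    """Write a GraderConfig as a canonical (sorted-key) YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: GraderConfig) -> str:
    """Stable sha256 of the canonical YAML form, for run manifests."""
    import hashlib

    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()
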