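"""Readers and writers for landmark point files, osteophyte masks and area tables.

Point files use an ASM-style text dialect::

    # subject_id: S0001
    # side: right
    # pixel_spacing_mm: 0.250000
    version: 1
    n_points: 129
    {
    123.456789 45.678901
    ...
    }

The three ``#`` header lines are a sidecar carrying scan metadata the bare
ASM format has no slot for; readers accept files without them if the missing
values are supplied as arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .config import N_LANDMARKS, GraderConfig, Side, Site

logger = logging.getLogger(__name__)

_COORD_FMT = "%.6f"


class PtsParseError(ValueError):
    """Raised on a malformed landmark point file."""


@dataclass(frozen=True)
class LandmarkSet:
    """129 ordered knee landmarks for one scan, in pixel coordinates.

    Points run along the bone contours of the distal femur, proximal tibia,
    proximal fibula and superior patella (x rightward, y downward, 0-based
    pixel centres). ``pixel_spacing_mm`` is the isotropic mm-per-pixel
    calibration.
    """

    subject_id: str
    side: Side
    points: np.ndarray  # shape (129, 2), float64
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (N_LANDMARKS, 2):
            raise PtsParseError(
                f"expected {N_LANDMARKS} points, found {pts.shape[0] if pts.ndim == 2 else '?'}"
            )
        if not np.all(np.isfinite(pts)):
            raise PtsParseError("landmark coordinates must be finite")
        if np.any(pts < 0):
            raise PtsParseError("landmark coordinates must be non-negative")
        if not (self.pixel_spacing_mm > 0):
            raise PtsParseError("pixel_spacing_mm must be positive")


@dataclass(frozen=True)
class SiteAnnotation:
    """One osteophyte site's annotation: a shaded mask or a precomputed area."""

    site: Site
    area_mm2: Optional[float] = None
    mask: Optional[np.ndarray] = None  # boolean raster
    pixel_spacing_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area_mm2 is None and self.mask is None:
            raise ValueError(f"annotation for {self.site.value} has neither mask nor area")
        if self.area_mm2 is not None and self.area_mm2 < 0:
            raise ValueError("area_mm2 must be non-negative")
        if self.mask is not None and self.pixel_spacing_mm is None:
            raise ValueError("mask annotation requires pixel_spacing_mm")


# -- point files -------------------------------------------------------------


def read_pts(
    path: Union[str, Path],
    *,
    pixel_spacing_mm: Optional[float] = None,
    side: Optional[Side] = None,
    subject_id: Optional[str] = None,
) -> LandmarkSet:
    """Parse a landmark point file.

    Sidecar header values may be overridden (or supplied, for bare ASM files)
    through the keyword arguments. ``subject_id`` defaults to the file stem.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_declared: Optional[int] = None
    coords: list[tuple[float, float]] = []
    in_body = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line == "{":
                in_body = True
                continue
            if line == "}":
                in_body = False
                continue
            if in_body:
                parts = line.split()
                if len(parts) != 2:
                    raise PtsParseError(
                        f"{path}:{lineno}: expected 'x y', got {line!r}"
                    )
                try:
                    coords.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise PtsParseError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
                continue
            if line.lower().startswith("version"):
                continue
            if line.lower().startswith("n_points"):
                try:
                    n_declared = int(line.split(":")[1])
                except (IndexError, ValueError) as exc:
                    raise PtsParseError(f"{path}:{lineno}: bad n_points line") from exc
                continue
            raise PtsParseError(f"{path}:{lineno}: unrecognised line {line!r}")

    if n_declared is None:
        raise PtsParseError(f"{path}: missing n_points declaration")
    if n_declared != len(coords):
        raise PtsParseError(
            f"{path}: n_points declares {n_declared} but file holds {len(coords)}"
        )
    if len(coords) != N_LANDMARKS:
        raise PtsParseError(
            f"{path}: expected {N_LANDMARKS} points, found {len(coords)}"
        )

    if pixel_spacing_mm is None:
        if "pixel_spacing_mm" not in meta:
            raise PtsParseError(
                f"{path}: no pixel_spacing_mm header and none supplied"
            )
        pixel_spacing_mm = float(meta["pixel_spacing_mm"])
    if side is None:
        side = Side(meta.get("side", "right"))
    if subject_id is None:
        subject_id = meta.get("subject_id", path.stem)

    return LandmarkSet(
        subject_id=subject_id,
        side=side,
        points=np.array(coords, dtype=float),
        pixel_spacing_mm=pixel_spacing_mm,
    )


def write_pts(lm: LandmarkSet, path: Union[str, Path]) -> None:
    """Write a LandmarkSet in canonical form (fixed 6-decimal coordinates)."""
    lines = [
        f"# subject_id: {lm.subject_id}",
        f"# side: {lm.side.value}",
        f"# pixel_spacing_mm: {_COORD_FMT % lm.pixel_spacing_mm}",
        "version: 1",
        f"n_points: {N_LANDMARKS}",
        "{",
    ]
    lines += [f"{_COORD_FMT % x} {_COORD_FMT % y}" for x, y in lm.points]
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- osteophyte masks --------------------------------------------------------


def read_mask(
    path: Union[str, Path],
    cfg: GraderConfig,
    pixel_spacing_mm: float,
) -> list[SiteAnnotation]:
    """Decode a colour-coded osteophyte shading raster into site annotations.

    Each site's pixels must match its configured RGB colour exactly; any
    other non-background colour is logged as a warning and ignored.  Sites
    with no matching pixels are absent from the result.
    """
    img = Image.open(path).convert("RGB")
    arr = np.asarray(img)
    annotations: list[SiteAnnotation] = []
    matched = np.zeros(arr.shape[:2], dtype=bool)
    for site, rgb in cfg.mask_color_map.items():
        m = np.all(arr == np.array(rgb, dtype=arr.dtype), axis=-1)
        matched |= m
        if m.any():
            annotations.append(
                SiteAnnotation(site=site, mask=m, pixel_spacing_mm=pixel_spacing_mm)
            )
    background = np.all(arr == 0, axis=-1)
    stray = int((~matched & ~background).sum())
    if stray:
        logger.warning(
            "%s: %d pixels in unmapped colours ignored", path, stray
        )
    return annotations


def write_mask(
    annotations: Sequence[SiteAnnotation],
    cfg: GraderConfig,
    shape: tuple[int, int],
    path: Union[str, Path],
) -> None:
    """Rasterise site masks into one RGB PNG using the configured colour map."""
    arr = np.zeros((*shape, 3), dtype=np.uint8)
    for ann in annotations:
        if ann.mask is None:
            raise ValueError(f"annotation for {ann.site.value} carries no mask")
        arr[ann.mask] = cfg.mask_color_map[ann.site]
    Image.fromarray(arr).save(path)


# -- per-site area tables ----------------------------------------------------


def read_area_table(path: Union[str, Path]) -> dict[str, list[SiteAnnotation]]:
    """Read a CSV of precomputed osteophyte areas.

    Expected columns: ``subject_id, site, area_mm2``. Returns a mapping from
    subject id to its annotations.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "site", "area_mm2"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"area table {path} must have columns {sorted(required)}"
        )
    out: dict[str, list[SiteAnnotation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            SiteAnnotation(site=Site(row.site), area_mm2=float(row.area_mm2))
        )
    return out
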