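"""Minimum joint-space-width (mJSW) measurement from landmark subsets.

The joint space width of a tibiofemoral compartment is the smallest distance
between the femoral and tibial articular contours. Each contour is available
only as an ordered landmark subset, so the operator here is the bidirectional
point-to-polyline minimum: every femoral landmark is projected onto the
tibial polyline and vice versa, and the global minimum is taken. A plain
closest-landmark-pair mode is available for replication studies
(``cfg.distance_mode = "point"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GraderConfig
from .io import LandmarkSet


@dataclass(frozen=True)
class JswMeasure:
    """Per-compartment minimum joint space width, in millimetres.

    ``medial_argmin``/``lateral_argmin`` record which landmark of one contour
    and which segment (or landmark, in point mode) of the other realised the
    minimum, as ``(contour, point_index, other_segment_index)`` with 0-based
    indices into the subset sequences.
    """

    medial_mjsw_mm: float
    lateral_mjsw_mm: float
    medial_argmin: tuple
    lateral_argmin: tuple


def compartment_subsets(
    lm: LandmarkSet, cfg: GraderConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Slice the four configured joint-surface subsets out of a landmark set.

    Returns (femur-medial, femur-lateral, tibia-medial, tibia-lateral) point
    arrays in contour order. Config ranges are 1-based inclusive.
    """

    def grab(rng: tuple[int, int]) -> np.ndarray:
        lo, hi = rng
        return lm.points[lo - 1 : hi]

    return (
        grab(cfg.femur_medial_idx),
        grab(cfg.femur_lateral_idx),
        grab(cfg.tibia_medial_idx),
        grab(cfg.tibia_lateral_idx),
    )


def _point_segment_distances(pts: np.ndarray, seg: np.ndarray) -> np.ndarray:
    """Distances from each point to each segment of a polyline.

    pts: (n, 2); seg: (m+1, 2) polyline vertices. Returns (n, m).
    """
    a = seg[:-1]  # (m, 2)
    d = seg[1:] - a  # (m, 2)
    len2 = np.einsum("ij,ij->i", d, d)  # (m,)
    diff = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nmj,mj->nm", diff, d) / len2
    t = np.where(len2 > 0, t, 0.0)
    t = np.clip(t, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * d[None, :, :]
    return np.linalg.norm(pts[:, None, :] - foot, axis=-1)


def min_polyline_distance(
    a: np.ndarray, b: np.ndarray, mode: str = "segment"
) -> tuple[float, tuple]:
    """Minimum distance between two landmark polylines, in input units.

    In ``"segment"`` mode this is the minimum over distances from every
    vertex of one polyline to the other polyline's segments, taken in both
    directions — symmetric, and never larger than the closest vertex pair.
    In ``"point"`` mode only vertex pairs are considered. Single-point inputs
    degenerate to the point-to-point distance in either mode.

    Returns ``(distance, argmin)`` where argmin is
    ``("a"|"b"|"pair", point_index, other_index)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or len(a) == 0 or len(b) == 0:
        raise ValueError("both point sequences must be non-empty (n, 2) arrays")

    pair = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(pair), pair.shape)
    best = float(pair[i, j])
    arg: tuple = ("pair", int(i), int(j))

    if mode == "point" or (len(a) == 1 and len(b) == 1):
        return best, arg

    if len(b) >= 2:
        dab = _point_segment_distances(a, b)
        i2, j2 = np.unravel_index(np.argmin(dab), dab.shape)
        if dab[i2, j2] < best:
            best, arg = float(dab[i2, j2]), ("a", int(i2), int(j2))
    if len(a) >= 2:
        dba = _point_segment_distances(b, a)
        i3, j3 = np.unravel_index(np.argmin(dba), dba.shape)
        if dba[i3, j3] < best:
            best, arg = float(dba[i3, j3]), ("b", int(i3), int(j3))
    return best, arg


def mjsw(lm: LandmarkSet, cfg: GraderConfig) -> JswMeasure:
    """Measure medial and lateral minimum joint space width for one scan.

    Distances are computed in pixels between the configured femoral and
    tibial subsets, then calibrated to millimetres with the scan's pixel
    spacing.
    """
    fm, fl, tm, tl = compartment_subsets(lm, cfg)
    d_med, arg_med = min_polyline_distance(fm, tm, mode=cfg.distance_mode)
    d_lat, arg_lat = min_polyline_distance(fl, tl, mode=cfg.distance_mode)
    s = lm.pixel_spacing_mm
    return JswMeasure(
        medial_mjsw_mm=d_med * s,
        lateral_mjsw_mm=d_lat * s,
        medial_argmin=arg_med,
        lateral_argmin=arg_lat,
    )


def height_normalize(
    mjsw_mm: float,
    height_cm: float,
    mean_height_cm: float,
    mode: str = "scale_to_mean",
) -> float:
    """Normalise an mJSW measurement for stature.

    The default rescales to the population mean height,
    ``mjsw × mean_height / height``, so a person of average height is
    unchanged and taller people (whose joints are proportionally wider) are
    scaled down. ``"divide_by_height"`` returns ``mjsw / height`` instead
    (units mm/cm), for sensitivity analyses.
    """
    if height_cm <= 0 or mean_height_cm <= 0:
        raise ValueError("heights must be positive")
    if mode == "scale_to_mean":
        return mjsw_mm * (mean_height_cm / height_cm)
    if mode == "divide_by_height":
        return mjsw_mm / height_cm
    raise ValueError(f"unknown height normalisation mode {mode!r}")
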