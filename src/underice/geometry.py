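"""Pixel-to-metric registration and shape descriptors.

The upward-looking camera is modelled as a pinhole with one laboratory
calibration constant ``k`` (mm per pixel per metre of standoff): at an
altimeter distance D the ground-sample distance is ``k * D`` millimetres per
pixel, 4.5 mm at one metre by default.  All aggregate measurements are
converted with the per-frame scale; tilt below the QC cut is small enough
that no projective correction is applied (it contributes to the stated
size-uncertainty budget instead).

Units follow the reporting convention of the survey tables: frame footprints
and region areas in m^2, aggregate lengths (ECD, axes) in cm, coverage as a
fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import CROP_HEIGHT, CROP_WIDTH, Frame, RegionDetection

__all__ = [
    "CameraCalib",
    "AggregateDetection",
    "FrameSummary",
    "pixel_scale",
    "ice_draft",
    "to_metric",
    "summarize_frame",
]


@dataclass(frozen=True)
class CameraCalib:
    """Single-constant pinhole calibration.

    k: mm per pixel per metre of standoff distance (default 4.5, i.e.
    4.5 mm ground-sample distance at 1 m from the ice).
    """

    k: float = 4.5
    native_size: tuple[int, int] = (288, 384)  # (rows, cols)
    crop_size: tuple[int, int] = (CROP_HEIGHT, CROP_WIDTH)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("calibration constant k must be positive")


@dataclass
class AggregateDetection:
    """Metric measurements of one detected aggregate."""

    frame_id: int
    region_id: int
    area: float  # m^2
    ecd: float  # cm, equivalent circular diameter
    perimeter: float | None = None  # m
    major: float | None = None  # cm
    minor: float | None = None  # cm
    eccentricity: float | None = None
    circularity: float | None = None
    measurable: bool = False
    clump_flag: bool = False


@dataclass
class FrameSummary:
    """Per-frame aggregate statistics over the analysed footprint."""

    frame_id: int
    n_aggregates: int
    footprint: float  # m^2
    abundance: float  # aggregates m^-2
    coverage: float  # fraction of footprint
    mean_ecd: float | None  # cm, measurable non-clump regions
    median_ecd: float | None
    mean_eccentricity: float | None
    x: float = float("nan")
    y: float = float("nan")
    draft: float = float("nan")  # m, depth - altimeter (clipped at 0)


def pixel_scale(altimeter_distance: float, calib: CameraCalib) -> float:
    """Metres per pixel at the given standoff distance (linear in distance)."""
    if altimeter_distance <= 0:
        raise ValueError("altimeter distance must be positive")
    return calib.k * altimeter_distance / 1000.0


def ice_draft(depth, altimeter_distance):
    """Ice draft (m) as vehicle depth minus acoustic distance to the ice.

    Sensor noise can make the difference slightly negative; such values are
    clipped to zero and a warning reports how many were clipped.  Accepts
    scalars or arrays.
    """
    depth = np.asarray(depth, dtype=float)
    dist = np.asarray(altimeter_distance, dtype=float)
    draft = depth - dist
    n_neg = int(np.sum(draft < 0))
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative ice-draft value(s) to 0", stacklevel=2)
        draft = np.clip(draft, 0.0, None)
    if draft.ndim == 0:
        return float(draft)
    return draft


def to_metric(region: RegionDetection, scale: float) -> AggregateDetection:
    """Convert a pixel-space region to metric units at ``scale`` m/px.

    Area scales with scale^2, lengths with scale.  ECD = 2 sqrt(area/pi);
    eccentricity = sqrt(1 - (minor/major)^2); circularity = 4 pi A / P^2
    (can exceed 1 slightly for small regions through perimeter
    discretisation).  Regions without an ellipse fit keep area and ECD only.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    area_m2 = region.pixel_area * scale * scale
    ecd_cm = 2.0 * math.sqrt(area_m2 / math.pi) * 100.0
    det = AggregateDetection(
        frame_id=region.frame_id,
        region_id=region.region_id,
        area=area_m2,
        ecd=ecd_cm,
        measurable=region.measurable,
        clump_flag=region.clump_flag,
    )
    if region.pixel_perimeter > 0:
        det.perimeter = region.pixel_perimeter * scale
        det.circularity = 4.0 * math.pi * area_m2 / det.perimeter**2
    if region.major_axis is not None and region.minor_axis is not None:
        det.major = region.major_axis * scale * 100.0
        det.minor = region.minor_axis * scale * 100.0
        ratio = min(region.minor_axis / region.major_axis, 1.0)
        det.eccentricity = math.sqrt(max(1.0 - ratio * ratio, 0.0))
    return det


def summarize_frame(
    detections: Sequence[AggregateDetection],
    frame: Frame,
    calib: CameraCalib,
) -> FrameSummary:
    """Frame-level abundance, coverage and size statistics.

    The footprint is the metric extent of the analysis crop at the frame's
    standoff.  All detections count toward abundance and coverage; only
    measurable, non-clump-flagged ones enter the size and shape statistics.
    """
    scale = pixel_scale(frame.altimeter, calib)
    rows, cols = calib.crop_size
    footprint = (rows * scale) * (cols * scale)
    if footprint <= 0:
        raise ValueError("zero frame footprint")
    n = len(detections)
    covered = sum(d.area for d in detections)
    sizes = [
        d.ecd for d in detections if d.measurable and not d.clump_flag
    ]
    eccs = [
        d.eccentricity
        for d in detections
        if d.measurable and not d.clump_flag and d.eccentricity is not None
    ]
    # per-frame clip of a slightly negative draft is routine sensor noise;
    # the aggregate count of clips is visible in the frame table instead
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        draft = ice_draft(frame.depth, frame.altimeter)
    return FrameSummary(
        frame_id=frame.frame_id,
        n_aggregates=n,
        footprint=footprint,
        abundance=n / footprint,
        coverage=covered / footprint,
        mean_ecd=float(np.mean(sizes)) if sizes else None,
        median_ecd=float(np.median(sizes)) if sizes else None,
        mean_eccentricity=float(np.mean(eccs)) if eccs else None,
        x=frame.x,
        y=frame.y,
        draft=draft,
    )
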