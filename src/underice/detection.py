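"""Aggregate detection in upward-looking under-ice frames.

The detector is a deliberately simple threshold classifier: under-ice algal
aggregates appear as dark patches against the bright, backlit ice underside,
so every pixel whose green-channel value falls in a low band (0-100 of 255 by
default) is classified as aggregate, the binary mask is labelled into
connected regions, and per-region pixel geometry is measured.  Frame-level
quality control removes frames taken too deep (the footprint becomes too
large and dim) or at excessive vehicle tilt (the flat-ice projection breaks
down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage import measure

__all__ = [
    "Frame",
    "RegionDetection",
    "QCReport",
    "crop_frame",
    "centered_crop_offset",
    "threshold_green",
    "label_regions",
    "qc_frames",
    "qc_regions",
    "flag_clumps",
    "NATIVE_WIDTH",
    "NATIVE_HEIGHT",
    "CROP_WIDTH",
    "CROP_HEIGHT",
    "GREEN_LO",
    "GREEN_HI",
    "MAX_DEPTH_M",
    "MAX_TILT_DEG",
    "MIN_SHAPE_PIXELS",
]

# Native sensor raster and the analysis crop that removes vignetted edges
# and the camera's on-screen overlay.
NATIVE_WIDTH = 384
NATIVE_HEIGHT = 288
CROP_WIDTH = 250
CROP_HEIGHT = 200

# Green-channel aggregate band (inclusive) on an 8-bit scale.
GREEN_LO = 0
GREEN_HI = 100

# Frame QC: strict inequalities, boundary values are retained.
MAX_DEPTH_M = 5.0
MAX_TILT_DEG = 10.0

# Regions covering more than this many pixels get full shape parameters.
MIN_SHAPE_PIXELS = 10


@dataclass
class Frame:
    """One still capture with its navigation record.

    ``altimeter`` is the acoustic distance from the vehicle to the ice
    underside (the standoff), the quantity that sets the pixel scale.
    ``x``/``y`` are floe-fixed coordinates in metres.
    """

    frame_id: int
    t: float
    depth: float
    tilt: float
    altimeter: float
    x: float
    y: float
    pixels: np.ndarray | None = None  # H x W x 3 uint8, or None before render

    def with_pixels(self, pixels: np.ndarray) -> "Frame":
        return replace(self, pixels=pixels)


@dataclass
class RegionDetection:
    """Pixel-space measurements of one connected aggregate region."""

    frame_id: int
    region_id: int
    pixel_area: int
    pixel_perimeter: float
    centroid: tuple[float, float]  # (row, col) in the analysed raster
    major_axis: float | None = None  # px, fitted-ellipse full axes
    minor_axis: float | None = None
    orientation: float | None = None  # rad
    solidity: float | None = None
    measurable: bool = False
    clump_flag: bool = False


@dataclass
class QCReport:
    """Frame quality-control bookkeeping."""

    n_input: int
    n_discarded_depth: int
    n_discarded_tilt: int
    n_discarded_manual: int
    n_valid: int
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_out = (
            self.n_discarded_depth
            + self.n_discarded_tilt
            + self.n_discarded_manual
        )
        if self.n_valid != self.n_input - n_out:
            raise ValueError("inconsistent QC counts")


def centered_crop_offset(
    frame_shape: tuple[int, int] = (NATIVE_HEIGHT, NATIVE_WIDTH),
    crop_shape: tuple[int, int] = (CROP_HEIGHT, CROP_WIDTH),
) -> tuple[int, int]:
    """(row, col) offset that centres the analysis crop in the native frame."""
    return ((frame_shape[0] - crop_shape[0]) // 2, (frame_shape[1] - crop_shape[1]) // 2)


def crop_frame(
    frame: Frame,
    width: int = CROP_WIDTH,
    height: int = CROP_HEIGHT,
    offset: tuple[int, int] | None = None,
) -> Frame:
    """Return the frame restricted to its analysis window.

    ``offset`` is (row, col) of the window's top-left corner; by default the
    window is centred.  Metadata is carried over unchanged.
    """
    if frame.pixels is None:
        raise ValueError("frame has no pixel data to crop")
    h, w = frame.pixels.shape[:2]
    if offset is None:
        offset = centered_crop_offset((h, w), (height, width))
    r0, c0 = offset
    if r0 < 0 or c0 < 0 or r0 + height > h or c0 + width > w:
        raise ValueError(
            f"crop window {height}x{width} at offset {offset} exceeds frame {h}x{w}"
        )
    return frame.with_pixels(frame.pixels[r0 : r0 + height, c0 : c0 + width])


def threshold_green(
    frame: Frame | np.ndarray, lo: int = GREEN_LO, hi: int = GREEN_HI
) -> np.ndarray:
    """Binary aggregate mask: True where lo <= green <= hi (inclusive)."""
    if lo > hi:
        raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
    pixels = frame.pixels if isinstance(frame, Frame) else frame
    if pixels is None:
        raise ValueError("frame has no pixel data")
    if pixels.ndim != 3 or pixels.shape[2] < 3:
        raise ValueError("expected an RGB raster")
    green = pixels[..., 1]
    return (green >= lo) & (green <= hi)


def label_regions(
    mask: np.ndarray,
    frame_id: int = -1,
    connectivity: int = 8,
) -> list[RegionDetection]:
    """Connected-component labelling of an aggregate mask.

    One :class:`RegionDetection` per component; fitted-ellipse axes and
    orientation come from skimage's second-moment ellipse.  Degenerate
    components (minor axis 0, e.g. single pixels or 1-px lines) carry no
    ellipse fields.  Perimeter is the boundary-step (Freeman chain) length so
    circularity is reproducible across runs.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    regions: list[RegionDetection] = []
    for props in measure.regionprops(labels):
        major = props.axis_major_length
        minor = props.axis_minor_length
        has_ellipse = minor > 0
        regions.append(
            RegionDetection(
                frame_id=frame_id,
                region_id=int(props.label),
                pixel_area=int(props.area),
                pixel_perimeter=float(props.perimeter),
                centroid=(float(props.centroid[0]), float(props.centroid[1])),
                major_axis=float(major) if has_ellipse else None,
                minor_axis=float(minor) if has_ellipse else None,
                orientation=float(props.orientation) if has_ellipse else None,
                solidity=float(props.solidity),
            )
        )
    return regions


def qc_frames(
    frames: Sequence[Frame],
    max_depth: float = MAX_DEPTH_M,
    max_tilt: float = MAX_TILT_DEG,
    blocklist: set[int] | None = None,
) -> tuple[list[Frame], QCReport]:
    """Discard frames taken deeper than ``max_depth`` or tilted beyond
    ``max_tilt`` (strict inequalities: boundary values are retained).

    ``blocklist`` holds frame ids discarded by manual review; frames with
    missing navigation are discarded with reason ``missing-nav`` (counted as
    manual discards).
    """
    blocklist = blocklist or set()
    valid: list[Frame] = []
    reasons: dict[int, str] = {}
    n_depth = n_tilt = n_manual = 0
    for fr in frames:
        if fr.frame_id in blocklist:
            n_manual += 1
            reasons[fr.frame_id] = "blocklist"
            continue
        nav = (fr.depth, fr.tilt, fr.altimeter)
        if any(v is None or not math.isfinite(v) for v in nav):
            n_manual += 1
            reasons[fr.frame_id] = "missing-nav"
            continue
        if fr.depth > max_depth:
            n_depth += 1
            reasons[fr.frame_id] = "depth"
            continue
        if abs(fr.tilt) > max_tilt:
            n_tilt += 1
            reasons[fr.frame_id] = "tilt"
            continue
        valid.append(fr)
    report = QCReport(
        n_input=len(frames),
        n_discarded_depth=n_depth,
        n_discarded_tilt=n_tilt,
        n_discarded_manual=n_manual,
        n_valid=len(valid),
        reasons=reasons,
    )
    return valid, report


def qc_regions(
    regions: Sequence[RegionDetection], min_shape_pixels: int = MIN_SHAPE_PIXELS
) -> tuple[list[RegionDetection], list[RegionDetection]]:
    """Partition regions into (measurable, detect-only).

    Regions covering strictly more than ``min_shape_pixels`` pixels get full
    shape parameters; smaller ones still count toward abundance and coverage.
    """
    measurable: list[RegionDetection] = []
    detect_only: list[RegionDetection] = []
    for r in regions:
        if r.pixel_area > min_shape_pixels and r.minor_axis is not None:
            r.measurable = True
            measurable.append(r)
        else:
            r.measurable = False
            detect_only.append(r)
    return measurable, detect_only


def flag_clumps(
    regions: Sequence[RegionDetection],
    solidity_min: float = 0.85,
    size_outlier_k: float = 10.0,
    min_solidity_area: int = 50,
) -> list[bool]:
    """Flag probable clumps of close-lying aggregates merged into one region.

    A region is flagged when its solidity (area over convex-hull area) drops
    below ``solidity_min`` — a merged dumbbell is strongly non-convex while a
    single aggregate ellipse is convex — or when its log10 area exceeds the
    sample median by more than ``size_outlier_k`` scaled median absolute
    deviations.  The solidity rule only applies to regions of at least
    ``min_solidity_area`` pixels: below that, discretisation alone makes
    thin ellipses ragged, and a merged clump of measurable aggregates is
    necessarily larger.  The size rule works on the log scale with a high
    default ``k`` because genuine aggregate sizes are heavy-tailed (power-law
    spectrum): it should catch only gross merge events, not the tail.
    Flagged regions are excluded from shape and size statistics downstream
    but keep counting toward abundance and coverage.
    """
    flags = [False] * len(regions)
    if not regions:
        return flags
    log_areas = np.log10([r.pixel_area for r in regions])
    if len(log_areas) >= 3 and np.isfinite(size_outlier_k):
        med = np.median(log_areas)
        mad = 1.4826 * np.median(np.abs(log_areas - med))
        size_cut = med + size_outlier_k * mad if mad > 0 else np.inf
    else:
        size_cut = np.inf
    for i, r in enumerate(regions):
        low_solidity = (
            r.solidity is not None
            and r.pixel_area >= min_solidity_area
            and r.solidity < solidity_min
        )
        oversize = math.log10(r.pixel_area) > size_cut
        flags[i] = bool(low_solidity or oversize)
        r.clump_flag = flags[i]
    return flags
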