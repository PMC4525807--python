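"""Synthetic under-ice scenes, aggregate fields and ROV surveys.

No public archive of upward-looking under-ice survey imagery exists, so every
stage of the processing chain is exercised against generated data with exact
ground truth.  The generator emulates the salient structure of such surveys:

* an ice floe with a smooth random draft field plus linear ridge keels,
  windowed-std roughness and a draft-dependent light transmittance;
* algal aggregates whose equivalent circular diameters follow a truncated
  power law (number spectra of marine aggregates are canonically power laws
  with slope near -3) and whose positions follow a Thomas parent-offspring
  cluster process, optionally attracted toward local draft minima, because
  buoyant aggregates collect in domes and level ice between ridge keels;
* a vehicle track (lawnmower or random walk) sampled at a fixed frame
  interval with noisy depth/tilt/position records and an altimeter standoff;
* 8-bit RGB frames in which aggregates are dark filled ellipses against a
  bright ice background with a lateral brightness gradient and pixel noise.

Everything is driven by one seeded generator per call, so a fixed seed gives
bit-identical scenes, fields, surveys and frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .detection import NATIVE_HEIGHT, NATIVE_WIDTH, Frame, centered_crop_offset
from .geometry import CameraCalib, pixel_scale

__all__ = [
    "IceSceneParams",
    "IceScene",
    "TrueAggregate",
    "SizeLaw",
    "Clustering",
    "SurveyParams",
    "RenderParams",
    "gen_ice_scene",
    "gen_aggregate_field",
    "simulate_survey",
    "render_frame",
    "sample_truncated_powerlaw",
    "truncated_powerlaw_cdf",
]


# ---------------------------------------------------------------------------
# Ice scene


@dataclass(frozen=True)
class IceSceneParams:
    """Parameters of the generated ice-draft field.

    Lengths are metres.  ``correlation_length`` sets the Gaussian smoothing
    of the random draft component; ridges are straight keels with Gaussian
    cross-section.  ``transmittance_decay`` is the exponential attenuation of
    light per metre of ice draft.
    """

    cell_size: float = 0.5
    mean_draft: float = 1.0
    draft_std: float = 0.3
    correlation_length: float = 10.0
    n_ridges: int = 2
    ridge_amplitude: float = 3.0
    ridge_width: float = 4.0
    roughness_window: int = 5  # cells, windowed-std box size
    transmittance_decay: float = 1.5  # m^-1


@dataclass
class IceScene:
    """Floe-fixed habitat fields on a regular raster.

    ``draft`` is positive-down ice draft (m); ``roughness`` the windowed
    standard deviation of draft (m); ``transmittance`` dimensionless in
    [0, 1].  All three share one shape; cell (i, j) is centred at
    ``((j + 0.5) * cell_size, (i + 0.5) * cell_size)`` with the origin at the
    floe-fixed (0, 0) corner.
    """

    extent: tuple[float, float]  # (Lx, Ly), m
    cell_size: float
    draft: np.ndarray
    roughness: np.ndarray
    transmittance: np.ndarray

    def _index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.draft.shape
        j = np.clip((np.asarray(x) / self.cell_size).astype(int), 0, nx - 1)
        i = np.clip((np.asarray(y) / self.cell_size).astype(int), 0, ny - 1)
        return i, j

    def draft_at(self, x, y):
        i, j = self._index(x, y)
        return self.draft[i, j]

    def transmittance_at(self, x, y):
        i, j = self._index(x, y)
        return self.transmittance[i, j]


def _windowed_std(a: np.ndarray, window: int) -> np.ndarray:
    mean = ndimage.uniform_filter(a, size=window, mode="nearest")
    mean_sq = ndimage.uniform_filter(a * a, size=window, mode="nearest")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return np.sqrt(var)


def gen_ice_scene(
    extent: tuple[float, float],
    params: IceSceneParams = IceSceneParams(),
    seed: int = 0,
) -> IceScene:
    """Generate a random ice scene over a ``(Lx, Ly)`` rectangle."""
    Lx, Ly = extent
    if Lx <= 0 or Ly <= 0:
        raise ValueError("scene extent must be positive in both directions")
    if params.cell_size <= 0:
        raise ValueError("cell size must be positive")
    rng = np.random.default_rng(seed)
    nx = max(int(round(Lx / params.cell_size)), 1)
    ny = max(int(round(Ly / params.cell_size)), 1)

    if params.draft_std > 0:
        noise = rng.standard_normal((ny, nx))
        sigma = params.correlation_length / params.cell_size
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
        sd = smooth.std()
        smooth = smooth / sd * params.draft_std if sd > 0 else smooth * 0.0
    else:
        smooth = np.zeros((ny, nx))
    draft = params.mean_draft + smooth

    # straight ridge keels with Gaussian cross-section
    if params.n_ridges > 0 and params.ridge_amplitude > 0:
        yy, xx = np.mgrid[0:ny, 0:nx]
        xm = (xx + 0.5) * params.cell_size
        ym = (yy + 0.5) * params.cell_size
        for _ in range(params.n_ridges):
            x0, y0 = rng.uniform(0, Lx), rng.uniform(0, Ly)
            theta = rng.uniform(0, math.pi)
            # signed distance to the ridge line through (x0, y0)
            dist = -(xm - x0) * math.sin(theta) + (ym - y0) * math.cos(theta)
            draft += params.ridge_amplitude * np.exp(
                -0.5 * (dist / params.ridge_width) ** 2
            )

    draft = np.clip(draft, 0.0, None)
    roughness = _windowed_std(draft, params.roughness_window)
    transmittance = np.clip(np.exp(-params.transmittance_decay * draft), 0.0, 1.0)
    return IceScene(
        extent=(float(Lx), float(Ly)),
        cell_size=params.cell_size,
        draft=draft,
        roughness=roughness,
        transmittance=transmittance,
    )


# ---------------------------------------------------------------------------
# Aggregate field


@dataclass
class TrueAggregate:
    """Ground-truth aggregate: position (m), ECD (cm), ellipse shape."""

    agg_id: int
    x: float
    y: float
    diameter: float  # cm
    eccentricity: float
    orientation: float  # rad
    type_label: Literal["rounded", "filamentous"]


@dataclass(frozen=True)
class SizeLaw:
    """Truncated power-law number distribution of ECDs, f(d) ~ d^b on
    [d_min, d_max] (cm); b < 0."""

    b: float = -3.0
    d_min: float = 2.0
    d_max: float = 30.0

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("power-law exponent b must be negative")
        if not (0 < self.d_min < self.d_max):
            raise ValueError("require 0 < d_min < d_max")


@dataclass(frozen=True)
class Clustering:
    """Thomas-process parameters: Poisson parents with intensity
    ``parent_intensity`` (m^-2), Poisson(mean_per_cluster) offspring per
    parent, isotropic Gaussian displacement with sd ``cluster_sd`` (m)."""

    parent_intensity: float = 0.05
    mean_per_cluster: float = 5.0
    cluster_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.parent_intensity <= 0 or self.mean_per_cluster <= 0 or self.cluster_sd <= 0:
            raise ValueError("clustering parameters must be positive")


def sample_truncated_powerlaw(
    rng: np.random.Generator, n: int, b: float, d_min: float, d_max: float
) -> np.ndarray:
    """Inverse-CDF sampling of f(d) ~ d^b truncated to [d_min, d_max]."""
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    u = rng.uniform(size=n)
    if math.isclose(b, -1.0):
        return d_min * (d_max / d_min) ** u
    e = b + 1.0
    return (d_min**e + u * (d_max**e - d_min**e)) ** (1.0 / e)


def truncated_powerlaw_cdf(d, b: float, d_min: float, d_max: float):
    """CDF of the truncated power law, for goodness-of-fit checks."""
    d = np.clip(np.asarray(d, dtype=float), d_min, d_max)
    if math.isclose(b, -1.0):
        return np.log(d / d_min) / np.log(d_max / d_min)
    e = b + 1.0
    return (d**e - d_min**e) / (d_max**e - d_min**e)


def _sample_eccentricity(
    rng: np.random.Generator, type_label: str
) -> float:
    if type_label == "filamentous":
        return float(rng.uniform(0.93, 0.995))
    return float(rng.uniform(0.55, 0.85))


def gen_aggregate_field(
    scene: IceScene,
    *,
    n: int | None = None,
    intensity: float | None = None,
    size_law: SizeLaw = SizeLaw(),
    clustering: Clustering | None = Clustering(),
    filamentous_fraction: float = 0.2,
    draft_affinity: float = 0.0,
    seed: int = 0,
) -> list[TrueAggregate]:
    """Place aggregates on the scene with known statistical structure.

    Exactly one of ``n`` (fixed count) and ``intensity`` (expected total
    density, m^-2) must be given.  With ``clustering=None`` positions are a
    homogeneous Poisson process; otherwise a Thomas cluster process with
    offspring wrapped onto the scene torus, so the realised count is exact
    and stationary in the window.  When ``intensity`` is combined with
    clustering it fixes the total density: the per-parent offspring mean
    becomes intensity / parent_intensity, overriding
    ``clustering.mean_per_cluster``.  ``draft_affinity`` (m^-1) biases offspring
    toward thin ice: a proposed position at draft ``z`` is accepted with
    probability exp(-draft_affinity * (z - z_min)) and redrawn otherwise
    (count-preserving rejection).  Diameters are i.i.d. from ``size_law``;
    types are a Bernoulli mixture of rounded (low eccentricity) and
    filamentous (eccentricity in [0.93, 0.995]) aggregates.
    """
    if (n is None) == (intensity is None):
        raise ValueError("give exactly one of n= or intensity=")
    rng = np.random.default_rng(seed)
    Lx, Ly = scene.extent
    area = Lx * Ly
    z_min = float(scene.draft.min())

    def accept(x: float, y: float) -> bool:
        if draft_affinity <= 0:
            return True
        z = float(scene.draft_at(x, y))
        return rng.uniform() < math.exp(-draft_affinity * (z - z_min))

    def draw_position(parent: tuple[float, float] | None) -> tuple[float, float]:
        for _ in range(500):
            if parent is None:
                x, y = rng.uniform(0, Lx), rng.uniform(0, Ly)
            else:
                assert clustering is not None
                x = (parent[0] + rng.normal(0, clustering.cluster_sd)) % Lx
                y = (parent[1] + rng.normal(0, clustering.cluster_sd)) % Ly
            if accept(x, y):
                return x, y
        return x, y  # affinity nearly degenerate: accept the last proposal

    positions: list[tuple[float, float]] = []
    if clustering is None:
        n_total = int(n) if n is not None else int(rng.poisson(intensity * area))
        positions = [draw_position(None) for _ in range(n_total)]
    else:
        n_parents = int(rng.poisson(clustering.parent_intensity * area))
        if n is not None:
            n_parents = max(n_parents, 1)
        parents = [(rng.uniform(0, Lx), rng.uniform(0, Ly)) for _ in range(n_parents)]
        if n is not None:
            owners = rng.integers(0, n_parents, size=int(n))
            positions = [draw_position(parents[k]) for k in owners]
        else:
            per_cluster = intensity / clustering.parent_intensity
            for p in parents:
                for _ in range(int(rng.poisson(per_cluster))):
                    positions.append(draw_position(p))

    n_total = len(positions)
    diameters = sample_truncated_powerlaw(
        rng, n_total, size_law.b, size_law.d_min, size_law.d_max
    )
    aggregates: list[TrueAggregate] = []
    for i, ((x, y), d) in enumerate(zip(positions, diameters)):
        label = "filamentous" if rng.uniform() < filamentous_fraction else "rounded"
        aggregates.append(
            TrueAggregate(
                agg_id=i,
                x=float(x),
                y=float(y),
                diameter=float(d),
                eccentricity=_sample_eccentricity(rng, label),
                orientation=float(rng.uniform(0, math.pi)),
                type_label=label,
            )
        )
    return aggregates


# ---------------------------------------------------------------------------
# Survey simulation and rendering


@dataclass(frozen=True)
class SurveyParams:
    """Vehicle track and sensor-noise model.

    The vehicle flies at ``nominal_standoff`` metres below the local ice
    underside; the altimeter reads the true standoff while the depth sensor
    reads draft + standoff + N(0, depth_noise); recorded floe-fixed positions
    get N(0, position_noise_sd) error per axis; tilt records are
    |N(0, tilt_noise)| degrees.
    """

    track_type: Literal["lawnmower", "random-walk"] = "lawnmower"
    speed: float = 0.5  # m s^-1
    frame_interval: float = 5.0  # s, one still every 5 s
    nominal_standoff: float = 1.0  # m
    depth_noise: float = 0.05  # m, sd
    tilt_noise: float = 3.0  # deg, sd of half-normal tilt
    position_noise_sd: float = 1.0  # m
    line_spacing: float = 10.0  # m, lawnmower line separation
    margin: float = 2.0  # m, keep-out from floe edges
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")


@dataclass(frozen=True)
class RenderParams:
    """Frame appearance.  Clean defaults keep every background pixel well
    above the green threshold band and every aggregate pixel inside it."""

    background_green_mean: float = 190.0
    gradient_amp: float = 25.0  # lateral brightness ramp, +- across columns
    noise_sd: float = 6.0
    aggregate_green: float = 40.0
    modulate_by_transmittance: bool = False

    def __post_init__(self) -> None:
        if self.aggregate_green >= self.background_green_mean:
            raise ValueError("empty dynamic range: aggregates as bright as background")


def _lawnmower_waypoints(extent, spacing, margin) -> list[tuple[float, float]]:
    Lx, Ly = extent
    xs = (margin, Lx - margin)
    pts: list[tuple[float, float]] = []
    y = margin
    k = 0
    while y <= Ly - margin + 1e-9:
        a, b = (xs[0], xs[1]) if k % 2 == 0 else (xs[1], xs[0])
        pts.append((a, y))
        pts.append((b, y))
        y += spacing
        k += 1
    return pts


def _track_positions(
    scene: IceScene, survey: SurveyParams, rng: np.random.Generator
) -> np.ndarray:
    """True vehicle positions, one per frame interval, shape (n, 2)."""
    step = survey.speed * survey.frame_interval
    Lx, Ly = scene.extent
    if survey.track_type == "lawnmower":
        wp = np.array(_lawnmower_waypoints(scene.extent, survey.line_spacing, survey.margin))
        seg = np.diff(wp, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        s = np.arange(0.0, total, step)
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
        return wp[idx] + seg[idx] * frac[:, None]
    if survey.track_type == "random-walk":
        n = int(((Lx - 2 * survey.margin) * (Ly - 2 * survey.margin)) ** 0.5 / step * 40)
        n = max(n, 10)
        pos = np.empty((n, 2))
        p = np.array([Lx / 2, Ly / 2])
        heading = rng.uniform(0, 2 * math.pi)
        for i in range(n):
            pos[i] = p
            heading += rng.normal(0, math.radians(25))
            q = p + step * np.array([math.cos(heading), math.sin(heading)])
            # reflect off the margin box
            lo = survey.margin
            for ax, hi in ((0, Lx - survey.margin), (1, Ly - survey.margin)):
                if q[ax] < lo or q[ax] > hi:
                    q[ax] = np.clip(2 * np.clip(q[ax], lo, hi) - q[ax], lo, hi)
                    heading = math.pi - heading if ax == 0 else -heading
            p = q
        return pos
    raise ValueError(f"unknown track type {survey.track_type!r}")


def _agg_arrays(aggregates: Sequence[TrueAggregate]) -> dict[str, np.ndarray]:
    """Vectorised aggregate geometry for fast per-frame culling."""
    x = np.array([a.x for a in aggregates])
    y = np.array([a.y for a in aggregates])
    d_m = np.array([a.diameter for a in aggregates]) / 100.0
    ecc = np.array([a.eccentricity for a in aggregates])
    ratio = np.sqrt(np.clip(1.0 - ecc**2, 1e-6, None))  # minor/major
    semi_major = (d_m / 2.0) / np.sqrt(ratio)
    return {"x": x, "y": y, "d_m": d_m, "ratio": ratio, "semi_major": semi_major}


def render_frame(
    frame_geometry: Frame,
    scene: IceScene | None,
    aggregates: Sequence[TrueAggregate],
    calib: CameraCalib,
    rendering: RenderParams = RenderParams(),
    rng: np.random.Generator | None = None,
    truth_rows: list[dict] | None = None,
    _arrays: dict[str, np.ndarray] | None = None,
) -> Frame:
    """Render the native 8-bit RGB raster for one frame geometry.

    Aggregates are filled ellipses (area pi (d/2)^2, axis ratio from the true
    eccentricity) projected through the pinhole model at the recorded
    altimeter distance.  The background green level is a lateral ramp
    ``mean + amp * (2c/(W-1) - 1)`` plus Gaussian pixel noise; red and blue
    are fixed affine functions of green (the detector only reads green).
    When ``truth_rows`` is given, one row per rendered aggregate instance is
    appended with its pixel centre and crop-visibility flags.
    """
    rng = rng or np.random.default_rng(0)
    H, W = NATIVE_HEIGHT, NATIVE_WIDTH
    scale = pixel_scale(frame_geometry.altimeter, calib)  # m per px

    bg = rendering.background_green_mean
    if rendering.modulate_by_transmittance and scene is not None:
        t = float(scene.transmittance_at(frame_geometry.x, frame_geometry.y))
        t_ref = float(scene.transmittance.mean()) or 1.0
        bg = bg * min(max(t / t_ref, 0.3), 1.3)
    cols = np.arange(W, dtype=float)
    ramp = 2.0 * cols / (W - 1) - 1.0
    green = np.tile(bg + rendering.gradient_amp * ramp, (H, 1))

    cx, cy = frame_geometry.x, frame_geometry.y
    half_w = W / 2 * scale
    half_h = H / 2 * scale
    r0_crop, c0_crop = centered_crop_offset()
    from .detection import CROP_HEIGHT, CROP_WIDTH

    arrays = _arrays if _arrays is not None else _agg_arrays(aggregates)
    if len(aggregates):
        visible = np.nonzero(
            (np.abs(arrays["x"] - cx) <= half_w + arrays["semi_major"])
            & (np.abs(arrays["y"] - cy) <= half_h + arrays["semi_major"])
        )[0]
    else:
        visible = np.array([], dtype=int)

    for k in visible:
        agg = aggregates[k]
        d_m = float(arrays["d_m"][k])
        ratio = float(arrays["ratio"][k])
        semi_major = float(arrays["semi_major"][k])
        col = (W - 1) / 2.0 + (agg.x - cx) / scale
        row = (H - 1) / 2.0 - (agg.y - cy) / scale
        a_px = semi_major / scale
        b_px = (d_m / 2.0) * math.sqrt(ratio) / scale
        rr, cc = skdraw.ellipse(
            row, col, b_px, a_px, shape=(H, W), rotation=agg.orientation
        )
        if rr.size == 0:
            continue
        green[rr, cc] = rendering.aggregate_green
        if truth_rows is not None:
            in_crop = (
                row + a_px >= r0_crop
                and row - a_px < r0_crop + CROP_HEIGHT
                and col + a_px >= c0_crop
                and col - a_px < c0_crop + CROP_WIDTH
            )
            fully_in_crop = (
                row - a_px >= r0_crop
                and row + a_px < r0_crop + CROP_HEIGHT
                and col - a_px >= c0_crop
                and col + a_px < c0_crop + CROP_WIDTH
            )
            truth_rows.append(
                {
                    "frame_id": frame_geometry.frame_id,
                    "agg_id": agg.agg_id,
                    "row_px": row,
                    "col_px": col,
                    "radius_px": a_px,
                    "n_pixels": int(rr.size),
                    "diameter_cm": agg.diameter,
                    "eccentricity": agg.eccentricity,
                    "type_label": agg.type_label,
                    "in_crop": bool(in_crop),
                    "fully_in_crop": bool(fully_in_crop),
                }
            )

    if rendering.noise_sd > 0:
        green = green + rng.normal(0.0, rendering.noise_sd, size=green.shape)
    green = np.clip(green, 0, 255)
    pixels = np.empty((H, W, 3), dtype=np.uint8)
    pixels[..., 0] = np.clip(green * 0.93, 0, 255).astype(np.uint8)
    pixels[..., 1] = green.astype(np.uint8)
    pixels[..., 2] = np.clip(green * 1.05, 0, 255).astype(np.uint8)
    return frame_geometry.with_pixels(pixels)


def simulate_survey(
    scene: IceScene,
    aggregates: Sequence[TrueAggregate],
    survey: SurveyParams = SurveyParams(),
    calib: CameraCalib = CameraCalib(),
    rendering: RenderParams | None = RenderParams(),
    track: np.ndarray | None = None,
) -> tuple[list[Frame], pd.DataFrame]:
    """Fly a survey over the scene and return (frames, ground-truth table).

    One frame per ``frame_interval`` along the track.  With
    ``rendering=None`` the frames carry geometry only (no pixels) and the
    truth table is empty; otherwise every rendered aggregate instance yields
    one truth row linked to its :class:`TrueAggregate` id.  An explicit
    ``track`` (n x 2 true positions) overrides the built-in track generator.
    """
    rng = np.random.default_rng(survey.seed)
    if track is None:
        track = _track_positions(scene, survey, rng)
    frames: list[Frame] = []
    truth_rows: list[dict] | None = [] if rendering is not None else None
    arrays = _agg_arrays(aggregates) if rendering is not None else None
    for i, (tx, ty) in enumerate(np.atleast_2d(track)):
        draft = float(scene.draft_at(tx, ty))
        depth = draft + survey.nominal_standoff + (
            rng.normal(0, survey.depth_noise) if survey.depth_noise > 0 else 0.0
        )
        tilt = (
            abs(rng.normal(0, survey.tilt_noise)) if survey.tilt_noise > 0 else 0.0
        )
        ex = rng.normal(0, survey.position_noise_sd) if survey.position_noise_sd > 0 else 0.0
        ey = rng.normal(0, survey.position_noise_sd) if survey.position_noise_sd > 0 else 0.0
        geom = Frame(
            frame_id=i,
            t=i * survey.frame_interval,
            depth=depth,
            tilt=tilt,
            altimeter=survey.nominal_standoff,
            x=float(tx + ex),
            y=float(ty + ey),
        )
        if rendering is not None:
            # render with the true camera position; the noisy one is recorded
            true_geom = Frame(
                frame_id=i, t=geom.t, depth=depth, tilt=tilt,
                altimeter=survey.nominal_standoff, x=float(tx), y=float(ty),
            )
            rendered = render_frame(
                true_geom, scene, aggregates, calib, rendering, rng, truth_rows,
                _arrays=arrays,
            )
            geom = geom.with_pixels(rendered.pixels)
        frames.append(geom)
    truth = pd.DataFrame(
        truth_rows
        if truth_rows
        else [],
        columns=[
            "frame_id", "agg_id", "row_px", "col_px", "radius_px", "n_pixels",
            "diameter_cm", "eccentricity", "type_label", "in_crop", "fully_in_crop",
        ],
    )
    return frames, truth
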