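"""End-to-end survey processing: simulate/load -> detect -> metric ->
grid -> biovolume -> spatial statistics, under one config and one seed.

Every stage logs one structured line (counts in/out) so the QC funnel can be
audited, and all intermediate tables can be written to an artifact directory.
The pipeline is pure with respect to (config, seed): a fixed seed reproduces
every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import gridding, io, spatial_stats, synthetic
from .biomass import CARBON_DENSITY_MG_PER_ML, BiovolumeEstimate, estimate_all_methods
from .detection import (
    CROP_HEIGHT,
    CROP_WIDTH,
    GREEN_HI,
    GREEN_LO,
    MAX_DEPTH_M,
    MAX_TILT_DEG,
    MIN_SHAPE_PIXELS,
    Frame,
    QCReport,
    RegionDetection,
    crop_frame,
    flag_clumps,
    label_regions,
    qc_frames,
    qc_regions,
    threshold_green,
)
from .geometry import AggregateDetection, CameraCalib, pixel_scale, summarize_frame, to_metric
from .validation import ValidationResult, validate_detections

logger = logging.getLogger("underice")

__all__ = [
    "DetectionConfig",
    "SimulationConfig",
    "RunConfig",
    "StationReport",
    "process_frames",
    "run_pipeline",
    "compare_stations",
]


@dataclass(frozen=True)
class DetectionConfig:
    green_lo: int = GREEN_LO
    green_hi: int = GREEN_HI
    crop_width: int = CROP_WIDTH
    crop_height: int = CROP_HEIGHT
    crop_offset: tuple[int, int] | None = None  # (row, col); centred if None
    connectivity: int = 8
    max_depth: float = MAX_DEPTH_M
    max_tilt: float = MAX_TILT_DEG
    min_shape_pixels: int = MIN_SHAPE_PIXELS
    solidity_min: float = 0.85
    size_outlier_k: float = 10.0
    min_solidity_area: int = 50


@dataclass(frozen=True)
class SimulationConfig:
    extent: tuple[float, float] = (80.0, 80.0)
    scene: synthetic.IceSceneParams = synthetic.IceSceneParams()
    intensity: float | None = 3.0  # aggregates m^-2 (expected)
    n: int | None = None
    size_law: synthetic.SizeLaw = synthetic.SizeLaw()
    clustering: synthetic.Clustering | None = synthetic.Clustering()
    filamentous_fraction: float = 0.2
    draft_affinity: float = 0.0
    survey: synthetic.SurveyParams = synthetic.SurveyParams()
    rendering: synthetic.RenderParams = synthetic.RenderParams()


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the field campaign's processing: 0-100 green threshold,
    250 x 200 crop, depth/tilt QC at 5 m / 10 deg (strict), 10-px shape
    cutoff, 3 x 3 m grid, 0.39 mg C ml^-1 carbon density.
    """

    seed: int = 0
    calib: CameraCalib = CameraCalib()
    detection: DetectionConfig = DetectionConfig()
    simulation: SimulationConfig = SimulationConfig()
    cell_size: float = gridding.CELL_SIZE_M
    carbon_density: float = CARBON_DENSITY_MG_PER_ML
    restricted_fit_d_min: float = 2.0  # cm, the "large aggregate" slope fit
    type_convention: str = "anchored"
    frames_dir: str | None = None  # load instead of simulate when set
    blocklist: tuple[int, ...] = ()
    write_frames: bool = False
    make_figures: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        sim_raw = dict(raw.get("simulation") or {})
        for key, cls in (
            ("scene", synthetic.IceSceneParams),
            ("size_law", synthetic.SizeLaw),
            ("survey", synthetic.SurveyParams),
            ("rendering", synthetic.RenderParams),
        ):
            if key in sim_raw and isinstance(sim_raw[key], dict):
                sim_raw[key] = cls(**sim_raw[key])
        if "clustering" in sim_raw and isinstance(sim_raw["clustering"], dict):
            sim_raw["clustering"] = synthetic.Clustering(**sim_raw["clustering"])
        if "extent" in sim_raw:
            sim_raw["extent"] = tuple(sim_raw["extent"])
        kwargs = dict(raw)
        kwargs["simulation"] = SimulationConfig(**sim_raw)
        if "detection" in kwargs and isinstance(kwargs["detection"], dict):
            kwargs["detection"] = DetectionConfig(**kwargs["detection"])
        if "calib" in kwargs and isinstance(kwargs["calib"], dict):
            kwargs["calib"] = CameraCalib(**kwargs["calib"])
        if "blocklist" in kwargs:
            kwargs["blocklist"] = tuple(kwargs["blocklist"])
        return RunConfig(**kwargs)

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return unpack(self)


@dataclass
class StationReport:
    """All station-level results of one pipeline run."""

    config: RunConfig
    qc: QCReport
    frames: pd.DataFrame  # valid-frame summaries with cell indices
    detections: pd.DataFrame  # per-aggregate metric table
    grid: pd.DataFrame  # cell raster
    biovolume: dict[str, BiovolumeEstimate]
    patchiness: spatial_stats.PatchinessResult | None
    size_fit: spatial_stats.SizeDistributionFit | None
    size_fit_restricted: spatial_stats.SizeDistributionFit | None
    mean_eccentricity: float | None
    validation: ValidationResult | None = None
    truth: pd.DataFrame | None = None

    def summary(self) -> dict:
        """Flat numeric summary of the run (what the report table prints)."""
        out: dict[str, float | None] = {
            "n_frames_valid": int(self.qc.n_valid),
            "n_detections": int(len(self.detections)),
            "abundance": float(self.frames["abundance"].mean()) if len(self.frames) else 0.0,
            "coverage_pct": 100.0 * float(self.frames["coverage"].mean()) if len(self.frames) else 0.0,
            "mean_eccentricity": self.mean_eccentricity,
        }
        for m, est in self.biovolume.items():
            out[f"V_{m}"] = est.V
            out[f"C_{m}"] = est.carbon
        out["lloyd_P"] = self.patchiness.P if self.patchiness else None
        out["slope"] = self.size_fit.b if self.size_fit else None
        out["slope_gt2cm"] = (
            self.size_fit_restricted.b if self.size_fit_restricted else None
        )
        if self.validation is not None:
            out["recall"] = self.validation.recall
            out["precision"] = self.validation.precision
            out["size_bias"] = self.validation.size_bias
        return out


def _detection_table(dets: Sequence[AggregateDetection], regions: Sequence[RegionDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_id": [d.frame_id for d in dets],
            "region_id": [d.region_id for d in dets],
            "pixel_area": [r.pixel_area for r in regions],
            "centroid_row": [r.centroid[0] for r in regions],
            "centroid_col": [r.centroid[1] for r in regions],
            "area_m2": [d.area for d in dets],
            "ecd": [d.ecd for d in dets],
            "perimeter_m": [d.perimeter for d in dets],
            "major_cm": [d.major for d in dets],
            "minor_cm": [d.minor for d in dets],
            "eccentricity": [d.eccentricity for d in dets],
            "circularity": [d.circularity for d in dets],
            "measurable": [d.measurable for d in dets],
            "clump_flag": [d.clump_flag for d in dets],
        }
    )


def process_frames(
    frames: Sequence[Frame],
    calib: CameraCalib,
    det_cfg: DetectionConfig = DetectionConfig(),
    blocklist: set[int] | None = None,
):
    """QC + detect + measure a list of frames.

    Returns (valid_frames, qc_report, regions, detections_df, summaries).
    """
    valid, qc = qc_frames(frames, det_cfg.max_depth, det_cfg.max_tilt, blocklist)
    logger.info("qc: %d frames in, %d valid", qc.n_input, qc.n_valid)
    all_regions: list[RegionDetection] = []
    all_dets: list[AggregateDetection] = []
    summaries = []
    for fr in valid:
        cropped = crop_frame(
            fr, det_cfg.crop_width, det_cfg.crop_height, det_cfg.crop_offset
        )
        mask = threshold_green(cropped, det_cfg.green_lo, det_cfg.green_hi)
        regions = label_regions(mask, fr.frame_id, det_cfg.connectivity)
        measurable, _ = qc_regions(regions, det_cfg.min_shape_pixels)
        flag_clumps(
            measurable, det_cfg.solidity_min, det_cfg.size_outlier_k,
            det_cfg.min_solidity_area,
        )
        scale = pixel_scale(fr.altimeter, calib)
        dets = [to_metric(r, scale) for r in regions]
        summaries.append(summarize_frame(dets, fr, calib))
        all_regions.extend(regions)
        all_dets.extend(dets)
    logger.info(
        "detect: %d regions (%d measurable) in %d frames",
        len(all_regions), sum(r.measurable for r in all_regions), len(valid),
    )
    return valid, qc, all_regions, _detection_table(all_dets, all_regions), summaries


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> StationReport:
    """Run the full chain and optionally write all artifacts to ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    truth = None
    scene = None
    if config.frames_dir is not None:
        frames = io.read_frames(config.frames_dir)
        logger.info("load: %d frames from %s", len(frames), config.frames_dir)
    else:
        sim = config.simulation
        scene = synthetic.gen_ice_scene(sim.extent, sim.scene, seed=int(sub[0]))
        aggregates = synthetic.gen_aggregate_field(
            scene,
            n=sim.n,
            intensity=sim.intensity if sim.n is None else None,
            size_law=sim.size_law,
            clustering=sim.clustering,
            filamentous_fraction=sim.filamentous_fraction,
            draft_affinity=sim.draft_affinity,
            seed=int(sub[1]),
        )
        survey = dataclasses.replace(sim.survey, seed=int(sub[2]))
        frames, truth = synthetic.simulate_survey(
            scene, aggregates, survey, config.calib, sim.rendering
        )
        logger.info(
            "simulate: %d aggregates, %d frames, %d rendered instances",
            len(aggregates), len(frames), len(truth),
        )

    valid, qc, regions, det_df, summaries = process_frames(
        frames, config.calib, config.detection, set(config.blocklist)
    )

    frame_df = gridding.frame_table(summaries)
    frame_df = gridding.assign_frames(frame_df, config.cell_size)
    cells = gridding.grid_average(frame_df, det_df, config.cell_size)
    cells = gridding.roughness_from_draft(cells)
    if scene is not None and len(cells):
        cells["transmittance"] = scene.transmittance_at(
            cells["x_center"].to_numpy(), cells["y_center"].to_numpy()
        )
    logger.info("grid: %d occupied cells", len(cells))

    biovol = estimate_all_methods(det_df, frame_df, cells, config.carbon_density)

    patch = None
    if len(cells) >= 2:
        counts = spatial_stats.cell_counts(cells, config.cell_size)
        if counts.mean() > 0:
            patch = spatial_stats.lloyd_patchiness(counts)

    sizes = det_df.loc[det_df["measurable"] & ~det_df["clump_flag"], "ecd"].to_numpy()
    median_standoff = (
        float(np.median([f.altimeter for f in valid])) if valid else 1.0
    )
    d_min_reliable = 3.0 * config.calib.k * median_standoff / 10.0  # cm
    size_fit = size_fit_r = None
    try:
        size_fit = spatial_stats.fit_size_distribution(sizes, d_min=d_min_reliable)
    except ValueError as e:
        logger.info("size fit rejected: %s", e)
    try:
        size_fit_r = spatial_stats.fit_size_distribution(
            sizes, d_min=config.restricted_fit_d_min
        )
    except ValueError as e:
        logger.info("restricted size fit rejected: %s", e)

    eccs = det_df.loc[
        det_df["measurable"] & ~det_df["clump_flag"], "eccentricity"
    ].dropna()
    mean_ecc = float(eccs.mean()) if len(eccs) else None

    val = None
    if truth is not None and len(truth):
        valid_ids = {f.frame_id for f in valid}
        ecd_map = {
            (int(r.frame_id), int(r.region_id)): float(r.ecd)
            for r in det_df.itertuples()
            if r.measurable and not r.clump_flag
        }
        offset = config.detection.crop_offset
        val = validate_detections(
            regions,
            truth[truth["frame_id"].isin(valid_ids)],
            ecd_by_region=ecd_map,
            crop_offset=offset,
            min_diameter_cm=d_min_reliable,
        )
        logger.info(
            "validate: recall %.3f precision %.3f over %d truths",
            val.recall, val.precision, val.n_truth,
        )

    report = StationReport(
        config=config, qc=qc, frames=frame_df, detections=det_df, grid=cells,
        biovolume=biovol, patchiness=patch, size_fit=size_fit,
        size_fit_restricted=size_fit_r, mean_eccentricity=mean_ecc,
        validation=val, truth=truth,
    )
    if out_dir is not None:
        _write_artifacts(report, frames, Path(out_dir))
    return report


def _round_half_away(x: float, decimals: int = 1) -> float:
    """Half-away-from-zero rounding used for presentation tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _write_artifacts(report: StationReport, frames: Sequence[Frame], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    io.write_qc_report(report.qc, out / "qc_report.json")
    report.frames.to_csv(out / "frames.csv", index=False, float_format="%.6g")
    io.write_detections_csv(report.detections, out / "detections.csv")
    report.grid.to_csv(out / "grid.csv", index=False, float_format="%.6g")
    if report.truth is not None:
        report.truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")
    summary = report.summary()
    rounded = {
        k: (_round_half_away(v) if isinstance(v, float) else v)
        for k, v in summary.items()
    }
    (out / "report.json").write_text(
        json.dumps({"full_precision": summary, "rounded": rounded}, indent=2,
                   default=float)
    )
    if cfg.write_frames:
        io.write_frames(frames, out / "frames")
    if cfg.make_figures:
        _write_figures(report, out)


def _write_figures(report: StationReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = report.grid
    if not len(cells):
        return
    fig, axes = plt.subplots(1, 3, figsize=(14, 4), constrained_layout=True)
    for ax, var, label in zip(
        axes,
        ["abundance", "draft", "roughness"],
        ["abundance (agg m$^{-2}$)", "ice draft (m)", "ice roughness (m)"],
    ):
        sc = ax.scatter(
            cells["x_center"], cells["y_center"], c=cells[var], s=18, marker="s",
            cmap="viridis",
        )
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_title(label)
        fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(out / "maps.png", dpi=120)
    plt.close(fig)


def compare_stations(
    report_early: StationReport, report_late: StationReport
) -> pd.DataFrame:
    """Per-method percent biovolume loss between two surveys of one floe,
    plus abundance and median-diameter change."""
    early, late = report_early.biovolume, report_late.biovolume
    if set(early) != set(late):
        raise ValueError("method sets differ between reports")
    rows = []
    for m in early:
        Ve, Vl = early[m].V, late[m].V
        loss = 100.0 * (Ve - Vl) / Ve if Ve > 0 else float("nan")
        rows.append({"method": m, "V_early": Ve, "V_late": Vl, "loss_pct": loss})
    df = pd.DataFrame(rows)
    for name, rep in (("early", report_early), ("late", report_late)):
        df[f"abundance_{name}"] = (
            float(rep.frames["abundance"].mean()) if len(rep.frames) else 0.0
        )
        sizes = rep.detections.loc[
            rep.detections["measurable"] & ~rep.detections["clump_flag"], "ecd"
        ]
        df[f"median_ecd_{name}"] = float(sizes.median()) if len(sizes) else float("nan")
    return df
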