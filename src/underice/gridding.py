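"""Floe-scale gridding of frame-level results.

Survey tracks overlap near the launch hole, so frame-level statistics would
double-count those areas.  All frame summaries are therefore averaged onto a
regular floe-fixed raster (3 x 3 m cells by default, matching the positioning
uncertainty): each occupied cell carries the arithmetic mean of the frame
summaries that fall in it, and diameter statistics pool the individual
measurable aggregates within the cell.  Cells without frames are absent, not
zero — no observation is not the same as no aggregates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AggregateDetection, FrameSummary

__all__ = [
    "CELL_SIZE_M",
    "assign_frames",
    "grid_average",
    "roughness_from_draft",
    "frame_table",
]

CELL_SIZE_M = 3.0


def frame_table(summaries: Sequence[FrameSummary]) -> pd.DataFrame:
    """Frame summaries as a DataFrame (one row per frame)."""
    return pd.DataFrame(
        {
            "frame_id": [s.frame_id for s in summaries],
            "x": [s.x for s in summaries],
            "y": [s.y for s in summaries],
            "n_aggregates": [s.n_aggregates for s in summaries],
            "footprint": [s.footprint for s in summaries],
            "abundance": [s.abundance for s in summaries],
            "coverage": [s.coverage for s in summaries],
            "mean_ecd": [s.mean_ecd for s in summaries],
            "median_ecd": [s.median_ecd for s in summaries],
            "mean_eccentricity": [s.mean_eccentricity for s in summaries],
            "draft": [s.draft for s in summaries],
        }
    )


def assign_frames(
    frames: pd.DataFrame,
    cell_size: float = CELL_SIZE_M,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Add half-open cell indices (i, j) = floor((pos - origin)/cell_size).

    ``frames`` needs columns x, y.  The origin defaults to the minimum
    observed (x, y), recorded by the pipeline for reproducibility.  j indexes
    x, i indexes y.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if origin is None:
        origin = (float(frames["x"].min()), float(frames["y"].min()))
    out = frames.copy()
    out["j"] = np.floor((out["x"] - origin[0]) / cell_size).astype(int)
    out["i"] = np.floor((out["y"] - origin[1]) / cell_size).astype(int)
    out.attrs["origin"] = origin
    out.attrs["cell_size"] = cell_size
    return out


def grid_average(
    frames: pd.DataFrame,
    detections: Sequence[AggregateDetection] | pd.DataFrame | None = None,
    cell_size: float = CELL_SIZE_M,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Average frame summaries per grid cell.

    ``frames`` is a :func:`frame_table` output, with or without cell indices
    (they are computed if absent).  Cell values are means over frames;
    ``mean_ecd``/``median_ecd`` are recomputed by pooling the measurable,
    non-clump-flagged aggregates of the cell's frames when ``detections`` is
    given (falling back to frame-level means otherwise).  Duplicating frames
    within a cell leaves every cell value unchanged.
    """
    if "i" not in frames.columns or "j" not in frames.columns:
        frames = assign_frames(frames, cell_size, origin)
    origin = frames.attrs.get("origin", origin)
    cell_size = frames.attrs.get("cell_size", cell_size)

    grouped = frames.groupby(["i", "j"], sort=True)
    cells = grouped.agg(
        n_frames=("frame_id", "size"),
        abundance=("abundance", "mean"),
        coverage=("coverage", "mean"),
        mean_ecd=("mean_ecd", "mean"),
        median_ecd=("median_ecd", "mean"),
        mean_eccentricity=("mean_eccentricity", "mean"),
        draft=("draft", "mean"),
    ).reset_index()

    if detections is not None:
        det = (
            detections
            if isinstance(detections, pd.DataFrame)
            else pd.DataFrame(
                {
                    "frame_id": [d.frame_id for d in detections],
                    "ecd": [d.ecd for d in detections],
                    "eccentricity": [d.eccentricity for d in detections],
                    "measurable": [d.measurable for d in detections],
                    "clump_flag": [d.clump_flag for d in detections],
                }
            )
        )
        det = det[det["measurable"] & ~det["clump_flag"]]
        det = det.merge(frames[["frame_id", "i", "j"]].drop_duplicates("frame_id"),
                        on="frame_id", how="inner")
        if len(det):
            pooled = det.groupby(["i", "j"])["ecd"].agg(["mean", "median"]).reset_index()
            pooled.columns = ["i", "j", "pooled_mean_ecd", "pooled_median_ecd"]
            cells = cells.merge(pooled, on=["i", "j"], how="left")
            cells["mean_ecd"] = cells.pop("pooled_mean_ecd").fillna(cells["mean_ecd"])
            cells["median_ecd"] = cells.pop("pooled_median_ecd").fillna(cells["median_ecd"])

    if origin is not None:
        cells["x_center"] = origin[0] + (cells["j"] + 0.5) * cell_size
        cells["y_center"] = origin[1] + (cells["i"] + 0.5) * cell_size
    cells.attrs["origin"] = origin
    cells.attrs["cell_size"] = cell_size
    return cells


def roughness_from_draft(cells: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Windowed-std surrogate for ice roughness on the cell raster.

    For each occupied cell, the standard deviation (ddof=1) of the mean
    drafts of the cells within the ``window x window`` neighbourhood (the
    cell and its 8 neighbours by default).  Cells with fewer than two draft
    samples in the window get no value.  This is a surrogate definition and
    is labelled as such in outputs.
    """
    by_idx = {(int(r.i), int(r.j)): float(r.draft) for r in cells.itertuples()}
    half = window // 2
    vals = []
    for r in cells.itertuples():
        neigh = [
            by_idx[(r.i + di, r.j + dj)]
            for di in range(-half, half + 1)
            for dj in range(-half, half + 1)
            if (r.i + di, r.j + dj) in by_idx
            and np.isfinite(by_idx[(r.i + di, r.j + dj)])
        ]
        vals.append(float(np.std(neigh, ddof=1)) if len(neigh) >= 2 else np.nan)
    out = cells.copy()
    out["roughness"] = vals
    return out
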