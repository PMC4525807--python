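"""Frame, navigation and report file formats.

Frames are 8-bit RGB PNGs named ``frame_<id>.png``; navigation is one CSV
with columns frame_id, t_s, depth_m, tilt_deg, altimeter_m, x_m, y_m.  The
synthetic generator writes the same dialect the detector reads.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import pandas as pd

from .detection import Frame, QCReport

__all__ = [
    "write_frames",
    "read_frames",
    "write_detections_csv",
    "write_qc_report",
    "NAV_COLUMNS",
]

NAV_COLUMNS = ["frame_id", "t_s", "depth_m", "tilt_deg", "altimeter_m", "x_m", "y_m"]


def write_frames(frames: Sequence[Frame], out_dir: str | Path) -> Path:
    """Write PNG frames plus ``nav.csv``; returns the nav path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for fr in frames:
        if fr.pixels is not None:
            iio.imwrite(out / f"frame_{fr.frame_id:06d}.png", fr.pixels)
        rows.append([fr.frame_id, fr.t, fr.depth, fr.tilt, fr.altimeter, fr.x, fr.y])
    nav = pd.DataFrame(rows, columns=NAV_COLUMNS)
    nav_path = out / "nav.csv"
    nav.to_csv(nav_path, index=False)
    return nav_path


def read_frames(frames_dir: str | Path, nav_csv: str | Path | None = None) -> list[Frame]:
    """Load frames listed in the navigation CSV; missing PNGs load as
    geometry-only frames."""
    frames_dir = Path(frames_dir)
    nav = pd.read_csv(nav_csv or frames_dir / "nav.csv")
    out: list[Frame] = []
    for r in nav.itertuples():
        png = frames_dir / f"frame_{int(r.frame_id):06d}.png"
        pixels = iio.imread(png) if png.exists() else None
        out.append(
            Frame(
                frame_id=int(r.frame_id), t=float(r.t_s), depth=float(r.depth_m),
                tilt=float(r.tilt_deg), altimeter=float(r.altimeter_m),
                x=float(r.x_m), y=float(r.y_m), pixels=pixels,
            )
        )
    return out


def write_detections_csv(detections: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    detections.to_csv(path, index=False, float_format="%.6g")
    return path


def write_qc_report(report: QCReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dataclasses.asdict(report)
    payload["reasons"] = {str(k): v for k, v in report.reasons.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
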