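"""Ground-truth validation of the detection chain on synthetic surveys.

Synthetic frames come with a truth table of every rendered aggregate
instance (pixel centre, projected radius, crop-visibility flags).  Detected
regions are matched to truth by centroid distance; recall is truth-centric
(a truth instance counts as found if any detection lies within its matching
radius) and precision is detection-centric (a detection counts as true if
any truth instance lies within reach), so a merged pair of close-lying
aggregates degrades recall but not precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import RegionDetection, centered_crop_offset

__all__ = ["ValidationResult", "validate_detections"]


@dataclass
class ValidationResult:
    recall: float
    precision: float
    n_truth: int  # fully-visible truth instances
    n_detections: int
    size_bias: float | None  # mean fractional ECD error of matched pairs
    size_error_abs: float | None  # mean |fractional error|
    matches: pd.DataFrame | None = None


def validate_detections(
    regions: Sequence[RegionDetection],
    truth: pd.DataFrame,
    ecd_by_region: dict[tuple[int, int], float] | None = None,
    crop_offset: tuple[int, int] | None = None,
    min_diameter_cm: float = 0.0,
) -> ValidationResult:
    """Score detections against the rendered ground truth.

    ``regions`` carry centroids in cropped-raster coordinates; ``truth`` is
    the table from :func:`underice.synthetic.simulate_survey`.  Recall is
    computed over fully-in-crop truth instances with true diameter >=
    ``min_diameter_cm`` (instances below the resolvable size can be excluded
    from the recall denominator without hiding them from precision).
    ``ecd_by_region`` maps (frame_id, region_id) to measured ECD (cm) for
    the size-bias statistic.
    """
    if crop_offset is None:
        crop_offset = centered_crop_offset()
    r0, c0 = crop_offset

    det = pd.DataFrame(
        {
            "frame_id": [r.frame_id for r in regions],
            "region_id": [r.region_id for r in regions],
            "row": [r.centroid[0] + r0 for r in regions],
            "col": [r.centroid[1] + c0 for r in regions],
        }
    )
    truth_vis = truth[truth["in_crop"]] if len(truth) else truth

    matched_truth = 0
    n_truth = 0
    det_true = np.zeros(len(det), dtype=bool)
    match_rows = []
    for fid, tgrp in truth_vis.groupby("frame_id"):
        dgrp = det[det["frame_id"] == fid]
        drows = dgrp["row"].to_numpy()
        dcols = dgrp["col"].to_numpy()
        for t in tgrp.itertuples():
            tol = max(4.0, 1.5 * t.radius_px)
            if len(dgrp):
                dist = np.hypot(drows - t.row_px, dcols - t.col_px)
                k = int(np.argmin(dist))
                hit = dist[k] <= tol
            else:
                hit = False
            countable = t.fully_in_crop and t.diameter_cm >= min_diameter_cm
            if countable:
                n_truth += 1
                if hit:
                    matched_truth += 1
            if hit:
                det_true[dgrp.index[k]] = True
                if countable:
                    key = (int(fid), int(dgrp.iloc[k]["region_id"]))
                    ecd = (ecd_by_region or {}).get(key)
                    match_rows.append(
                        {
                            "frame_id": int(fid),
                            "agg_id": int(t.agg_id),
                            "true_diameter_cm": float(t.diameter_cm),
                            "measured_ecd_cm": ecd,
                        }
                    )

    matches = pd.DataFrame(
        match_rows,
        columns=["frame_id", "agg_id", "true_diameter_cm", "measured_ecd_cm"],
    )
    size_bias = size_err = None
    if len(matches):
        ok = matches.dropna(subset=["measured_ecd_cm"])
        if len(ok):
            frac = (ok["measured_ecd_cm"] - ok["true_diameter_cm"]) / ok["true_diameter_cm"]
            size_bias = float(frac.mean())
            size_err = float(frac.abs().mean())

    return ValidationResult(
        recall=matched_truth / n_truth if n_truth else float("nan"),
        precision=float(det_true.mean()) if len(det) else float("nan"),
        n_truth=n_truth,
        n_detections=len(det),
        size_bias=size_bias,
        size_error_abs=size_err,
        matches=matches,
    )
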