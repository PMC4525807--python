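"""Published station summaries from the 2012 Central Arctic under-ice survey.

These are the printed station-level tables of the original ROV campaign
(eight ice stations, ICE-1 ... ICE-9, with ICE-1's floe revisited as ICE-9
seven weeks later): areal biovolume and carbon by estimation method, percent
cover and abundance, and mean aggregate properties with environmental
context.  The raw video is not archived, so these tables are inputs for
internal-consistency checks and worked examples, not quantities the package
recomputes from imagery.  Entries printed as "<0.01" are stored as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "STATIONS",
    "biovolume_table",
    "carbon_table",
    "coverage_percent",
    "station_properties",
]

STATIONS = ["ICE-1", "ICE-2", "ICE-3", "ICE-5", "ICE-6", "ICE-7", "ICE-8", "ICE-9"]

_NA = np.nan

_VOLUME = {
    # ml m^-2 per station, printed to the precision shown
    "global_mean":    [0.4, 2.1, 0.02, 0.03, 0.04, 10.4, 1.1, 0.03],
    "global_median":  [0.2, 0.5, _NA, 0.01, 0.01, 4.8, 0.5, 0.01],
    "gridded_mean":   [2.5, 6.0, 0.7, 0.3, 0.4, 16.8, 6.5, 0.3],
    "gridded_median": [0.9, 1.4, 0.5, 0.1, 0.2, 21.9, 4.1, 0.3],
    "raster_cells":   [5.2, 16.3, 4.7, 1.6, 3.0, 38.6, 6.9, 1.7],
    "aggregate_list": [2.2, 20.4, 0.2, 0.5, 0.7, 52.5, 6.9, 0.4],
}

_CARBON = {
    # mg C m^-2 per station
    "global_mean":    [0.2, 0.8, 0.01, 0.01, 0.02, 4.0, 0.4, 0.01],
    "global_median":  [0.1, 0.2, _NA, _NA, _NA, 1.9, 0.2, _NA],
    "gridded_mean":   [1.0, 2.3, 0.3, 0.1, 0.1, 6.5, 2.5, 0.1],
    "gridded_median": [0.4, 0.5, 0.2, 0.03, 0.07, 8.5, 1.6, 0.1],
    "raster_cells":   [2.0, 6.4, 1.8, 0.6, 1.2, 15.0, 2.7, 0.7],
    "aggregate_list": [0.8, 8.0, 0.1, 0.2, 0.3, 20.4, 2.7, 0.1],
}

_COVERAGE_PCT = [0.026, 0.062, 0.005, 0.003, 0.008, 0.163, 0.093, 0.004]

_PROPERTIES = {
    "latitude":        [84.00, 83.95, 82.86, 82.88, 85.06, 87.93, 88.83, 84.35],
    "longitude":       [30.00, 76.85, 109.86, 130.76, 122.52, 60.95, 58.53, 17.73],
    "abundance":       [2.8, 5.6, 0.4, 0.3, 1.1, 3.8, 16.0, 0.4],  # agg m^-2
    "abundance_full":  [2.85, 5.69, 0.48, 0.32, 1.13, 3.85, 16.07, 0.41],
    "diameter_median": [2.1, 2.0, 3.4, 2.1, 1.6, 3.5, 2.0, 1.5],  # cm
    "diameter_mean":   [2.5, 2.9, 4.1, 2.9, 2.2, 4.0, 2.4, 2.1],
    "circularity":     [0.79, 0.77, 0.66, 0.70, 0.68, 0.64, 0.71, 0.84],
    "eccentricity":    [0.79, 0.81, 0.89, 0.87, 0.85, 0.88, 0.87, 0.76],
    "patchiness":      [11.5, 9.2, 67.4, 17.9, 74.0, 3.1, 3.3, 5.2],
    "slope":           [-1.9, -2.2, -1.3, -1.7, -2.3, -2.2, -3.1, -1.6],
    "slope_gt2cm":     [-3.0, -3.0, -0.6, -1.2, -2.0, -3.2, -3.9, -1.0],
    "slope_gt2cm_low_r2": [False, False, True, True, True, False, False, True],
}


def biovolume_table() -> pd.DataFrame:
    """Printed areal biovolume (ml m^-2), methods x stations."""
    return pd.DataFrame(_VOLUME, index=STATIONS).T


def carbon_table() -> pd.DataFrame:
    """Printed areal carbon (mg C m^-2), methods x stations."""
    return pd.DataFrame(_CARBON, index=STATIONS).T


def coverage_percent() -> pd.Series:
    """Printed aggregate percent cover per station (full-dataset analysis)."""
    return pd.Series(_COVERAGE_PCT, index=STATIONS, name="coverage_pct")


def station_properties() -> pd.DataFrame:
    """Printed station-mean aggregate properties and environment."""
    return pd.DataFrame(_PROPERTIES, index=STATIONS)
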