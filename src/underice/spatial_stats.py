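"""Patchiness, size-distribution and station-level statistics.

Patchiness of the gridded aggregate counts is quantified with Lloyd's mean
crowding m* = m + (s^2/m - 1) and index of patchiness P = m*/m, where m and
s^2 are the mean and variance of per-cell counts: P is about 1 for random
(Poisson) dispersion and grows with clustering.  Aggregate size spectra are
fitted as a power law f(d) = c d^b on logarithmically binned number
densities; the characteristic slope b sits near -3 for typical marine
particle fields.  Station-scale aggregate-type composition is a linear map
of mean eccentricity between the observed extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PatchinessResult",
    "SizeDistributionFit",
    "TypeFractions",
    "lloyd_patchiness",
    "cell_counts",
    "fit_size_distribution",
    "type_fractions",
    "station_correlations",
    "R2_FLAG_THRESHOLD",
]

R2_FLAG_THRESHOLD = 0.8


@dataclass
class PatchinessResult:
    m: float  # mean count per cell
    m_star: float  # mean crowding
    P: float  # Lloyd's index of patchiness
    n_cells: int


@dataclass
class SizeDistributionFit:
    b: float  # characteristic slope
    c: float  # normalisation constant (number density at d = 1 cm)
    r_squared: float
    d_min: float  # cm, lower fit bound
    n: int  # diameters entering the fit
    flagged: bool  # True when r_squared < 0.8
    n_bins_used: int = 0


@dataclass
class TypeFractions:
    eps_station: float
    eps_min: float
    eps_max: float
    f_spherical: float
    f_elong: float
    convention: str = "anchored"


def lloyd_patchiness(cell_counts: Iterable[float], ddof: int = 1) -> PatchinessResult:
    """Lloyd's mean crowding and index of patchiness from per-cell counts.

    m* = m + (s^2/m - 1) with s^2 the sample variance (``ddof=1`` by
    default, Lloyd's variance-estimate form; ``ddof=0`` gives exactly the
    per-individual mean number of same-cell neighbours), and P = m*/m.
    """
    x = np.asarray(list(cell_counts), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two cells")
    m = float(x.mean())
    if m <= 0:
        raise ValueError("mean count is zero; patchiness undefined")
    s2 = float(x.var(ddof=ddof))
    m_star = m + (s2 / m - 1.0)
    return PatchinessResult(m=m, m_star=m_star, P=m_star / m, n_cells=int(x.size))


def cell_counts(cells: pd.DataFrame, cell_size: float | None = None) -> np.ndarray:
    """Integer aggregate counts per occupied grid cell.

    Reconstructed as cell mean abundance x cell area, rounded to the nearest
    integer — the gridded raster stores frame-averaged densities, not raw
    counts.
    """
    if cell_size is None:
        cell_size = cells.attrs.get("cell_size")
    if cell_size is None:
        raise ValueError("cell_size unknown; pass it explicitly")
    ab = cells["abundance"].dropna().to_numpy(dtype=float)
    return np.rint(ab * cell_size * cell_size).astype(int)


def _binned_spectrum(
    d: np.ndarray, d_min: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced number-density spectrum: (bin geometric centres, density)."""
    d_max = d.max()
    edges = np.logspace(np.log10(d_min), np.log10(d_max * (1 + 1e-9)), n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (widths * d.size)
    keep = counts > 0
    return centers[keep], density[keep]


def fit_size_distribution(
    diameters: Sequence[float] | np.ndarray,
    d_min: float | None = None,
    n_bins: int = 16,
    method: Literal["binned-ls", "mle"] = "binned-ls",
) -> SizeDistributionFit:
    """Fit the power-law number size distribution f(d) = c d^b.

    Default: counts in logarithmically spaced bins above ``d_min`` are
    normalised by bin width to a number-density spectrum and fitted by least
    squares on log10(density) vs log10(d) over non-empty bins.  The fit is
    flagged when R^2 < 0.8.  ``method="mle"`` instead maximises the
    truncated-Pareto likelihood on [d_min, max(d)] (R^2 is then still
    reported from the binned spectrum, for comparability).

    Requires at least 20 diameters above ``d_min`` and non-degenerate spread.
    """
    d = np.asarray(diameters, dtype=float)
    if d_min is None:
        d_min = float(d.min()) if d.size else 0.0
    d = d[d >= d_min]
    if d.size < 20:
        raise ValueError(f"need >= 20 diameters above d_min, got {d.size}")
    if np.isclose(d.min(), d.max()):
        raise ValueError("degenerate sample: all diameters identical")

    centers, density = _binned_spectrum(d, d_min, n_bins)
    if centers.size < 3:
        raise ValueError("fewer than 3 non-empty bins; cannot fit a slope")
    lr = stats.linregress(np.log10(centers), np.log10(density))
    b_ls, c_ls, r2 = float(lr.slope), float(10 ** lr.intercept), float(lr.rvalue**2)

    if method == "binned-ls":
        b, c = b_ls, c_ls
    elif method == "mle":
        d_max = float(d.max())
        log_d_sum = float(np.log(d).sum())

        def negll(b: float) -> float:
            if np.isclose(b, -1.0):
                logZ = np.log(np.log(d_max / d_min))
            else:
                e = b + 1.0
                logZ = np.log(abs((d_max**e - d_min**e) / e))
            return -(b * log_d_sum - d.size * logZ)

        res = optimize.minimize_scalar(negll, bounds=(-8.0, -0.05), method="bounded")
        b = float(res.x)
        c = c_ls
    else:
        raise ValueError(f"unknown fit method {method!r}")

    return SizeDistributionFit(
        b=b, c=c, r_squared=r2, d_min=float(d_min), n=int(d.size),
        flagged=bool(r2 < R2_FLAG_THRESHOLD), n_bins_used=int(centers.size),
    )


def type_fractions(
    station_mean_eps: float,
    eps_min: float,
    eps_max: float,
    convention: Literal["anchored", "literal"] = "anchored",
) -> TypeFractions:
    """Aggregate-type fractions from station mean eccentricity.

    The survey-wide extremes of station mean eccentricity coincide with
    stations hosting purely rounded (eps_min) and purely filamentous
    (eps_max) aggregates, so composition is mapped linearly between them.
    Under the default ``anchored`` convention high eccentricity means
    elongated: f_elong = (eps - eps_min)/(eps_max - eps_min).  The
    ``literal`` convention is the mirror image with the two labels swapped
    (the assignment that some reports print), provided for comparison.
    """
    if eps_min >= eps_max:
        raise ValueError("require eps_min < eps_max")
    if not (eps_min <= station_mean_eps <= eps_max):
        raise ValueError("station eccentricity outside [eps_min, eps_max]")
    t = (station_mean_eps - eps_min) / (eps_max - eps_min)
    if convention == "anchored":
        f_elong, f_spherical = t, 1.0 - t
    elif convention == "literal":
        f_spherical, f_elong = t, 1.0 - t
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return TypeFractions(
        eps_station=station_mean_eps, eps_min=eps_min, eps_max=eps_max,
        f_spherical=f_spherical, f_elong=f_elong, convention=convention,
    )


def station_correlations(
    station_table: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r and two-sided p for requested variable pairs across stations.

    Stations with either variable missing are dropped pairwise; pairs with
    fewer than 3 complete stations or a constant column yield no row.  No
    multiplicity correction is applied.
    """
    rows = []
    for xcol, ycol in pairs:
        sub = station_table[[xcol, ycol]].dropna()
        if len(sub) < 3:
            continue
        x = sub[xcol].to_numpy(dtype=float)
        y = sub[ycol].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"x": xcol, "y": ycol, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows, columns=["x", "y", "r", "p", "n"])
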