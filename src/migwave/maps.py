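"""Inversion of fitted curves to percentile passage dates and isochrone maps.

Given the per-cell intercept and slope (alpha_j, beta_j) of the cloglog
curve, the day by which a proportion p of migrants has passed cell j is

    t_j(p) = (cloglog(p) - alpha_j) / beta_j.

Surfaces are built for p in {5%, 15%, 50%, 85%} and interpolated to a
regular lat/lon raster by triangulated linear interpolation of cell-centre
dates (no extrapolation outside the convex hull).  Movement-segment maps
connect successive encounters of the same individual, keeping displacements
between 1 and 8 degrees of latitude or longitude — the range comparable to
what the isochrones resolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.optimize import brentq

from migwave.links import cloglog
from migwave.model import CarFit

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (0.05, 0.15, 0.50, 0.85)


def invert_date(alpha_j: float, beta_j: float, p: float) -> float:
    """Day at which the fitted cumulative curve reaches proportion p.

    Uses only the cell's intercept and slope (the printed inversion); for
    the variant that also solves through the autocovariate term see
    :func:`invert_date_with_autocov`.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly between 0 and 1 (link undefined at ends)")
    if beta_j == 0:
        raise ValueError("beta_j = 0: no temporal progression to invert")
    return float((cloglog(p) - alpha_j) / beta_j)


def invert_date_with_autocov(fit: CarFit, cell_id: str, p: float, A_of_t,
                             bracket: tuple[float, float] = (-200.0, 600.0)) -> float:
    """Solve cloglog(p) = alpha_j + beta_j t + gamma A(t) by root finding.

    ``A_of_t`` is a callable giving the (step-interpolated) autocovariate of
    the cell at day t.  Provided as a documented alternative to the default
    inversion, which drops the autocovariate term.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly between 0 and 1")
    aj, bj = fit.coef_for(cell_id)
    if fit.gamma is None:
        raise ValueError("fit has no autocovariate coefficient")
    target = float(cloglog(p))

    def f(t):
        return aj + bj * t + fit.gamma * float(A_of_t(t)) - target

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError("root not bracketed; widen the bracket")
    return float(brentq(f, lo, hi, xtol=1e-8))


def percentile_surface(
    fit: CarFit,
    p: float,
    cells: pd.DataFrame,
    window_days: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-cell passage dates t_j(p) for one percentile.

    Parameters
    ----------
    fit
        Converged CAR fit.
    p
        Proportion in (0, 1).
    cells
        Cell table with ``cell_id``, ``center_lat``, ``center_lon``.
    window_days
        Optional (first, last) day of the seasonal window; dates falling
        outside are retained but flagged ``extrapolated``.

    Returns
    -------
    DataFrame (cell_id, center_lat, center_lon, p, date, extrapolated,
    excluded).  Cells with non-positive slope get ``excluded=True`` and a
    missing date: their curve never rises, so no passage date exists.
    """
    if not fit.converged:
        raise ValueError("refusing to invert an unconverged fit")
    coef = fit.cell_coefs.merge(
        cells[["cell_id", "center_lat", "center_lon"]], on="cell_id")
    dates = np.full(len(coef), np.nan)
    excluded = coef["beta_j"].to_numpy(float) <= 0
    ok = ~excluded
    dates[ok] = (float(cloglog(p)) - coef.loc[ok, "alpha_j"].to_numpy(float)) \
        / coef.loc[ok, "beta_j"].to_numpy(float)
    if excluded.any():
        logger.warning("cells with beta_j <= 0 excluded from %s%% surface: %s",
                       int(round(100 * p)),
                       sorted(coef.loc[excluded, "cell_id"]))
    extrap = np.zeros(len(coef), dtype=bool)
    if window_days is not None:
        lo, hi = window_days
        extrap = ok & ((dates < lo) | (dates > hi))
    out = coef[["cell_id", "center_lat", "center_lon"]].copy()
    out["p"] = p
    out["date"] = dates
    out["extrapolated"] = extrap
    out["excluded"] = excluded
    return out


def interpolate_surface(
    cell_dates: pd.DataFrame,
    resolution: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triangulated linear interpolation of cell dates onto a raster.

    Parameters
    ----------
    cell_dates
        Rows with ``center_lat``, ``center_lon``, ``date`` (cells excluded
        from the surface, i.e. missing dates, are ignored).
    resolution
        Raster step in degrees.

    Returns
    -------
    (lon_axis, lat_axis, raster) with raster shape (n_lat, n_lon); NaN
    outside the convex hull of the cell centres (no extrapolation).
    """
    df = cell_dates.dropna(subset=["date"])
    if len(df) < 3:
        raise ValueError("need at least 3 cells with dates to interpolate")
    pts = df[["center_lon", "center_lat"]].to_numpy(float)
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("cell centres are collinear; cannot triangulate")
    vals = df["date"].to_numpy(float)
    lon_axis = np.arange(pts[:, 0].min(), pts[:, 0].max() + resolution / 2, resolution)
    lat_axis = np.arange(pts[:, 1].min(), pts[:, 1].max() + resolution / 2, resolution)
    glon, glat = np.meshgrid(lon_axis, lat_axis)
    raster = griddata(pts, vals, (glon, glat), method="linear")
    return lon_axis, lat_axis, raster


@dataclass(frozen=True)
class MovementSegment:
    """Displacement between two successive encounters of one individual."""

    ring_id: str
    from_lat: float
    from_lon: float
    from_day: int
    to_lat: float
    to_lon: float
    to_day: int

    @property
    def dlat(self) -> float:
        return self.to_lat - self.from_lat

    @property
    def dlon(self) -> float:
        return self.to_lon - self.from_lon


def movement_segments(
    records: pd.DataFrame,
    min_deg: float = 1.0,
    max_deg: float = 8.0,
) -> pd.DataFrame:
    """Movement segments between successive encounters of individuals.

    For each ring_id with at least two encounters in the (already
    window-filtered) records, consecutive encounters ordered by day-of-year
    (years pooled) yield one segment each; segments are kept when
    ``min_deg < max(|dlat|, |dlon|) < max_deg`` (strict bounds) — shorter
    ones carry no directional information at cell scale, longer ones
    clutter the map.
    """
    segs = []
    for rid, grp in records.groupby("ring_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("day", kind="mergesort")
        lat = grp["lat"].to_numpy(float)
        lon = grp["lon"].to_numpy(float)
        day = grp["day"].to_numpy(int)
        for i in range(len(grp) - 1):
            dlat = lat[i + 1] - lat[i]
            dlon = lon[i + 1] - lon[i]
            disp = max(abs(dlat), abs(dlon))
            if min_deg < disp < max_deg:
                segs.append((rid, lat[i], lon[i], day[i],
                             lat[i + 1], lon[i + 1], day[i + 1], dlat, dlon))
    return pd.DataFrame(
        segs,
        columns=["ring_id", "from_lat", "from_lon", "from_day",
                 "to_lat", "to_lon", "to_day", "dlat", "dlon"],
    )


def write_ascii_grid(lon_axis, lat_axis, raster, path) -> None:
    """ESRI ASCII-grid style text raster (rows north to south)."""
    step = float(lon_axis[1] - lon_axis[0]) if len(lon_axis) > 1 else 1.0
    header = (
        f"ncols {len(lon_axis)}\n"
        f"nrows {len(lat_axis)}\n"
        f"xllcorner {lon_axis[0] - step / 2:.6f}\n"
        f"yllcorner {lat_axis[0] - step / 2:.6f}\n"
        f"cellsize {step:.6f}\n"
        f"NODATA_value -9999\n"
    )
    body = np.where(np.isnan(raster), -9999.0, raster)[::-1]
    lines = "\n".join(" ".join(f"{v:.3f}" for v in row) for row in body)
    with open(path, "w") as fh:
        fh.write(header + lines + "\n")


def plot_surface(lon_axis, lat_axis, raster, path, title: str = "",
                 cmap: str = "viridis") -> None:
    """Filled-contour isochrone map with a day-of-year colour scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    cf = ax.contourf(lon_axis, lat_axis, raster, levels=12, cmap=cmap)
    ax.contour(lon_axis, lat_axis, raster, levels=12, colors="k", linewidths=0.4)
    cb = fig.colorbar(cf, ax=ax)
    cb.set_label("day of year (1 Jan = 1)")
    ax.set_xlabel("longitude (deg E)")
    ax.set_ylabel("latitude (deg N)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
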