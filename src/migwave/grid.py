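"""Analysis lattice: cell assignment, eligibility and queen adjacency.

The study area is tiled with square lat/lon cells anchored so that cell
edges fall at integer multiples of the cell size from the south-east corner
of the study region (latitude 26 N, longitude 26 E); only encounters north
of that latitude and west of that longitude enter the analysis.  The
British Isles use 1.5 degree cells, western Europe and north Africa 4 degree
cells.  A cell is eligible for curve fitting when it holds encounters on at
least four distinct days.  Adjacency is the queen configuration: the up-to-8
lattice neighbours sharing an edge or a corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GridSpec:
    """Square lat/lon lattice anchored at a south-east corner.

    Cells are half-open intervals [south, north) x [west, east); the anchor
    latitude edge is closed (a record exactly at ``lat_min`` falls in row 0)
    and the anchor longitude edge is open (records at ``lon_max`` are
    outside, "west of" the anchor meridian).  Optional outer bounds clip the
    study region.
    """

    cell_size_deg: float
    lat_min: float = 26.0
    lon_max: float = 26.0
    lat_max: float | None = None
    lon_min: float | None = None

    def __post_init__(self):
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    def cell_index(self, lat: float, lon: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside.

        Rows count northward from ``lat_min``; columns count eastward, with
        col 0 the westmost column compatible with ``lon_min`` when given,
        otherwise raw westward offsets from ``lon_max`` negated (callers
        only compare indices, absolute values are anchored by the data).
        """
        if lat < self.lat_min or lon >= self.lon_max:
            return None
        if self.lat_max is not None and lat >= self.lat_max:
            return None
        if self.lon_min is not None and lon < self.lon_min:
            return None
        s = self.cell_size_deg
        row = math.floor((lat - self.lat_min) / s)
        # eastward index; negative west of the anchor, left-closed edges
        col = math.floor((lon - self.lon_max) / s)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size_deg
        lat = self.lat_min + (row + 0.5) * s
        lon = self.lon_max + (col + 0.5) * s
        return lat, lon

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(south, west, north, east) edges of the cell."""
        s = self.cell_size_deg
        south = self.lat_min + row * s
        west = self.lon_max + col * s
        return south, west, south + s, west + s


def british_isles_grid() -> GridSpec:
    """1.5 degree lattice clipped to the British Isles region."""
    return GridSpec(cell_size_deg=1.5, lat_min=26.0, lon_max=26.0,
                    lat_max=62.0, lon_min=-11.5)


def west_europe_nafrica_grid() -> GridSpec:
    """4 degree lattice over western Europe and north Africa."""
    return GridSpec(cell_size_deg=4.0, lat_min=26.0, lon_max=26.0,
                    lat_max=62.0, lon_min=-18.0)


def _letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (column labels, west to east)."""
    out = ""
    i = int(i)
    while True:
        out = chr(ord("A") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out


def assign_cells(records: pd.DataFrame, grid: GridSpec) -> tuple[pd.DataFrame, int]:
    """Annotate records with lattice indices and cell labels.

    Parameters
    ----------
    records
        DataFrame with at least ``lat``, ``lon`` columns (``day`` is carried
        through).
    grid
        The lattice.

    Returns
    -------
    (annotated, n_dropped)
        Copy of the in-bounds rows with ``cell_row``, ``cell_col`` and
        ``cell_id`` columns, and the count of records outside the grid
        bounds (dropped).  Cell labels are letter+number with letters
        indexing columns west to east and numbers rows south to north,
        anchored at the westmost/southmost occupied cell.
    """
    lat = records["lat"].to_numpy(float)
    lon = records["lon"].to_numpy(float)
    s = grid.cell_size_deg
    inside = (lat >= grid.lat_min) & (lon < grid.lon_max)
    if grid.lat_max is not None:
        inside &= lat < grid.lat_max
    if grid.lon_min is not None:
        inside &= lon >= grid.lon_min
    out = records.loc[inside].copy()
    row = np.floor((out["lat"].to_numpy(float) - grid.lat_min) / s).astype(int)
    col = np.floor((out["lon"].to_numpy(float) - grid.lon_max) / s).astype(int)
    out["cell_row"] = row
    out["cell_col"] = col
    out["cell_id"] = cell_labels(row, col)
    return out, int((~inside).sum())


def cell_labels(row: np.ndarray, col: np.ndarray) -> list[str]:
    """Cosmetic letter+number labels from lattice indices.

    Letters index columns west to east, numbers rows south to north,
    both starting at the minimum occupied index.
    """
    row = np.asarray(row)
    col = np.asarray(col)
    if len(row) == 0:
        return []
    r0 = row.min()
    c0 = col.min()
    return [f"{_letters(c - c0)}{r - r0 + 1}" for r, c in zip(row, col)]


def build_cell_table(assigned: pd.DataFrame, grid: GridSpec,
                     min_distinct_dates: int = 4) -> pd.DataFrame:
    """Per-cell summary: counts, distinct encounter dates, eligibility.

    A cell is eligible when it holds encounters on at least
    ``min_distinct_dates`` distinct days — the minimum for interpolating a
    two-parameter cloglog curve with any support.
    """
    grp = assigned.groupby(["cell_id", "cell_row", "cell_col"], as_index=False).agg(
        n_records=("day", "size"),
        n_distinct_dates=("day", "nunique"),
    )
    centers = [grid.cell_center(r, c) for r, c in zip(grp["cell_row"], grp["cell_col"])]
    grp["center_lat"] = [c[0] for c in centers]
    grp["center_lon"] = [c[1] for c in centers]
    grp["eligible"] = grp["n_distinct_dates"] >= min_distinct_dates
    return grp.sort_values(["cell_row", "cell_col"]).reset_index(drop=True)


def eligible_cells(table: pd.DataFrame) -> set[str]:
    """Cell ids with at least four distinct encounter dates.

    Raises
    ------
    ValueError
        If no cell is eligible (nothing to model).
    """
    ids = set(table.loc[table["eligible"], "cell_id"])
    if not ids:
        raise ValueError("no eligible cells (every cell has < 4 distinct dates)")
    return ids


def queen_adjacency(table: pd.DataFrame,
                    restrict_to_eligible: bool = True) -> dict[str, set[str]]:
    """Queen-configuration adjacency among cells of one lattice.

    Two cells are neighbours when they share an edge or a corner, i.e.
    their lattice indices differ by at most 1 in each direction (not both
    0).  By default only eligible cells participate: data-poor cells have
    no observed cumulative proportions to contribute to the autocovariate.
    Set ``restrict_to_eligible=False`` to include all cells in the table.
    """
    sub = table.loc[table["eligible"]] if restrict_to_eligible else table
    pos = {cid: (r, c) for cid, r, c in
           zip(sub["cell_id"], sub["cell_row"], sub["cell_col"])}
    by_rc = {rc: cid for cid, rc in pos.items()}
    adj: dict[str, set[str]] = {cid: set() for cid in pos}
    for cid, (r, c) in pos.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                other = by_rc.get((r + dr, c + dc))
                if other is not None:
                    adj[cid].add(other)
    return adj


def cell_table_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def cells_to_geojson(table: pd.DataFrame, grid: GridSpec, path: str | Path) -> None:
    """Write cell polygons as GeoJSON for mapping."""
    import json

    feats = []
    for _, r in table.iterrows():
        south, west, north, east = grid.cell_bounds(int(r["cell_row"]), int(r["cell_col"]))
        ring = [[west, south], [east, south], [east, north], [west, north], [west, south]]
        feats.append({
            "type": "Feature",
            "properties": {k: (bool(r[k]) if k == "eligible" else r[k])
                           for k in ("cell_id", "n_records", "n_distinct_dates", "eligible")},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
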