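"""Per-cell cumulative arrival series and the spatial autocovariate.

For cell j, pooling encounters over all years, n_jt is the cumulated number
of individuals encountered in j up to and including day t, N_j the window
total, and p_jt = n_jt / N_j the cumulative proportion — an empirical CDF
evaluated at the cell's observation days.  The autocovariate A_jt is the
count-weighted average proportion already past the neighbouring cells at
day t:

    A_jt = sum_{k in dj} w_k p_kt,     w_k = N_k / N_dj,

where dj is the queen neighbourhood of j and N_dj the total count over it.
A neighbour's proportion at a day it was not observed is its empirical CDF
value there: last observation carried forward, 0 before its first
observation day.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def cumulative_series(assigned: pd.DataFrame, cells: set[str] | None = None) -> pd.DataFrame:
    """Build the per-cell cumulative series, pooled across years.

    Parameters
    ----------
    assigned
        Records with ``cell_id`` and ``day`` columns (filtered to the
        seasonal window, assigned to cells).
    cells
        Eligible cell ids; rows from other cells are dropped.  If None all
        cells present are used.

    Returns
    -------
    DataFrame with one row per (cell_id, observed day): columns ``cell_id``,
    ``day``, ``n`` (cumulative count), ``N`` (cell total), ``p`` (= n/N).
    Days are sorted ascending within cells and p reaches 1 at each cell's
    last observed day.

    Raises
    ------
    ValueError
        If a retained cell has fewer than 4 distinct days (eligibility was
        violated upstream).
    """
    df = assigned if cells is None else assigned[assigned["cell_id"].isin(cells)]
    counts = (
        df.groupby(["cell_id", "day"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["cell_id", "day"], kind="mergesort")
    )
    bad = counts.groupby("cell_id")["day"].nunique()
    bad = bad[bad < 4]
    if len(bad):
        raise ValueError(
            f"cells with < 4 distinct days reached cumulation: {sorted(bad.index)}"
        )
    counts["n"] = counts.groupby("cell_id")["count"].cumsum()
    totals = counts.groupby("cell_id")["count"].sum().rename("N")
    out = counts.merge(totals, on="cell_id")
    out["p"] = out["n"] / out["N"]
    return out[["cell_id", "day", "n", "N", "p"]].reset_index(drop=True)


def neighbor_weights(series: pd.DataFrame,
                     adjacency: dict[str, set[str]]) -> dict[str, dict[str, float]]:
    """Count weights w_k = N_k / N_dj for each cell's neighbourhood.

    Weights use the window-total count of each neighbour, so they are
    constant over the season and sum to 1 whenever the neighbourhood is
    non-empty.
    """
    totals = series.groupby("cell_id")["N"].first()
    weights: dict[str, dict[str, float]] = {}
    for j, nbrs in adjacency.items():
        present = [k for k in nbrs if k in totals.index]
        tot = float(totals.loc[present].sum()) if present else 0.0
        if tot > 0:
            weights[j] = {k: float(totals.loc[k]) / tot for k in present}
        else:
            weights[j] = {}
    return weights


def _step_cdf(days: np.ndarray, p: np.ndarray):
    """Empirical-CDF evaluator: LOCF, 0 before the first observation day."""
    def f(t):
        idx = np.searchsorted(days, t, side="right") - 1
        out = np.where(idx >= 0, p[np.clip(idx, 0, len(p) - 1)], 0.0)
        return out
    return f


def autocovariate(series: pd.DataFrame,
                  adjacency: dict[str, set[str]]) -> pd.DataFrame:
    """Fill the autocovariate column A_jt on the cumulative series.

    For each cell j and each of its observation days t, A_jt is the
    count-weighted mean of the neighbours' cumulative proportions at t,
    each evaluated by step interpolation of its own series.  Cells with an
    empty (or data-free) neighbourhood get A = 0 and ``n_neighbors`` 0, and
    are logged.
    """
    weights = neighbor_weights(series, adjacency)
    cdfs = {
        cid: _step_cdf(grp["day"].to_numpy(float), grp["p"].to_numpy(float))
        for cid, grp in series.groupby("cell_id")
    }
    out = series.copy()
    out["A"] = 0.0
    out["n_neighbors"] = 0
    isolated = []
    for cid, grp in out.groupby("cell_id"):
        w = weights.get(cid, {})
        if not w:
            isolated.append(cid)
            continue
        t = grp["day"].to_numpy(float)
        A = np.zeros(len(t))
        for k, wk in w.items():
            A += wk * cdfs[k](t)
        out.loc[grp.index, "A"] = A
        out.loc[grp.index, "n_neighbors"] = len(w)
    if isolated:
        logger.info("cells with empty neighbourhood (A set to 0): %s",
                    sorted(isolated))
    return out
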