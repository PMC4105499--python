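"""Curve inversion, percentile surfaces, raster interpolation, segments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from migwave.links import cloglog
from migwave.maps import (
    interpolate_surface,
    invert_date,
    invert_date_with_autocov,
    movement_segments,
    percentile_surface,
)
from migwave.model import predict_proportion


def test_invert_date_closed_forms():
    # cloglog(1 - 1/e) = 0, so t = -alpha/beta
    p0 = 1 - np.exp(-1)
    assert invert_date(2.0, 0.5, p0) == pytest.approx(-4.0, abs=1e-9)
    assert invert_date(0.0, 1.0, 0.5) == pytest.approx(np.log(np.log(2)), abs=1e-12)


def test_invert_date_validation():
    with pytest.raises(ValueError, match="progression"):
        invert_date(0.0, 0.0, 0.5)
    for bad in (0.0, 1.0, -0.1, 1.1):
        with pytest.raises(ValueError):
            invert_date(0.0, 1.0, bad)


def test_invert_predict_round_trip(bi_fit):
    cid = bi_fit.cell_coefs["cell_id"].iloc[3]
    aj, bj = bi_fit.coef_for(cid)
    for p in np.linspace(0.01, 0.99, 99):
        t = invert_date(aj, bj, p)
        assert predict_proportion(bi_fit, cid, t) == pytest.approx(p, abs=1e-10)


@given(st.floats(-20, 5), st.floats(0.02, 2.0), st.floats(0.01, 0.99))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_invert_matches_grid_search(alpha, beta, p):
    """invert_date agrees with a brute-force 0.001-day grid argmin of
    |cloglog_inv(alpha + beta t) - p|."""
    t = invert_date(alpha, beta, p)
    grid = t + np.arange(-2.0, 2.0, 0.001)
    vals = np.abs(-np.expm1(-np.exp(alpha + beta * grid)) - p)
    t_grid = grid[np.argmin(vals)]
    assert abs(t - t_grid) <= 0.0011


def test_percentile_surface_monotone_and_flags(bi_sim, bi_fit):
    surfs = {p: percentile_surface(bi_fit, p, bi_sim["table"],
                                   window_days=(60, 181))
             for p in (0.05, 0.15, 0.5, 0.85)}
    merged = surfs[0.05][["cell_id", "date"]].rename(columns={"date": "d05"})
    for p, col in [(0.15, "d15"), (0.5, "d50"), (0.85, "d85")]:
        merged = merged.merge(
            surfs[p][["cell_id", "date"]].rename(columns={"date": col}),
            on="cell_id")
    ok = merged.dropna()
    assert (ok["d05"] < ok["d15"]).all()
    assert (ok["d15"] < ok["d50"]).all()
    assert (ok["d50"] < ok["d85"]).all()


def test_percentile_surface_accuracy_against_truth(bi_sim, bi_fit):
    """Median passage dates land near the generating truth at the shared
    fixture's moderate sample size (the printed inversion drops the
    gamma*A term, so precision tightens as counts grow — the tighter
    bound at larger N is exercised in the acceptance suite)."""
    surf = percentile_surface(bi_fit, 0.5, bi_sim["table"])
    m = surf.merge(bi_sim["truth"], on="cell_id")
    err = (m["date"] - m["t50"]).abs()
    assert err.mean() < 3.5


def test_surface_excludes_nonpositive_slope(bi_sim, bi_fit):
    import copy

    fit = copy.deepcopy(bi_fit)
    fit.cell_coefs.loc[0, "beta_j"] = -0.01
    surf = percentile_surface(fit, 0.5, bi_sim["table"])
    bad = surf[surf["excluded"]]
    assert len(bad) == 1 and np.isnan(bad["date"].iloc[0])


def test_inversion_through_autocovariate(bi_sim, bi_fit):
    """Root-finding through the full linear predictor agrees with the
    plain inversion when the autocovariate is held at the value that makes
    the two predictors equal, and differs smoothly otherwise."""
    cid = bi_fit.cell_coefs["cell_id"].iloc[5]
    t_plain = invert_date(*bi_fit.coef_for(cid), 0.5)
    t_zero = invert_date_with_autocov(bi_fit, cid, 0.5, lambda t: 0.0)
    assert t_zero == pytest.approx(t_plain, abs=1e-6)
    t_full = invert_date_with_autocov(bi_fit, cid, 0.5, lambda t: 0.5)
    assert t_full != pytest.approx(t_plain, abs=1e-3)
    assert abs(t_full - t_plain) < abs(bi_fit.gamma) * 0.5 / abs(
        bi_fit.coef_for(cid)[1]) + 1e-6


def test_interpolation_square_midpoint_and_nodes():
    cells = pd.DataFrame({
        "center_lon": [0.0, 1.0, 0.0, 1.0],
        "center_lat": [0.0, 0.0, 1.0, 1.0],
        "date": [100.0, 100.0, 120.0, 120.0],
    })
    lon, lat, raster = interpolate_surface(cells, resolution=0.5)
    i = np.argmin(np.abs(lat - 0.5))
    j = np.argmin(np.abs(lon - 0.5))
    assert raster[i, j] == pytest.approx(110.0)
    # nodes reproduced
    assert raster[0, 0] == pytest.approx(100.0)
    assert raster[-1, -1] == pytest.approx(120.0)
    # constant field stays constant
    lon, lat, flat = interpolate_surface(cells.assign(date=115.0), resolution=0.5)
    assert np.allclose(flat[np.isfinite(flat)], 115.0)


def test_interpolation_requires_noncollinear_cells():
    with pytest.raises(ValueError):
        interpolate_surface(pd.DataFrame({
            "center_lon": [0.0, 1.0], "center_lat": [0.0, 0.0],
            "date": [1.0, 2.0]}))
    with pytest.raises(ValueError, match="collinear"):
        interpolate_surface(pd.DataFrame({
            "center_lon": [0.0, 1.0, 2.0], "center_lat": [0.0, 0.0, 0.0],
            "date": [1.0, 2.0, 3.0]}))


def _recs(rows):
    return pd.DataFrame(rows, columns=["ring_id", "lat", "lon", "day"])


@pytest.mark.parametrize("to,kept", [
    ((54.0, 1.0), True),    # dlat 4: inside (1, 8)
    ((50.5, 0.5), False),   # max displacement 0.5: too short
    ((50.0, 9.0), False),   # dlon 9: too long
    ((51.0, 0.0), False),   # exactly 1 degree: strict bound
    ((58.0, 0.0), False),   # exactly 8 degrees: strict bound
])
def test_movement_segment_bounds(to, kept):
    recs = _recs([("X", 50.0, 0.0, 100), ("X", to[0], to[1], 120)])
    segs = movement_segments(recs)
    assert (len(segs) == 1) == kept


def test_movement_segments_successive_order_and_oracle():
    rng = np.random.default_rng(4)
    rows = []
    for i in range(40):
        k = rng.integers(1, 4)
        for j in range(k):
            rows.append((f"R{i}", rng.uniform(45, 60), rng.uniform(-5, 10),
                         int(rng.integers(60, 180))))
    recs = _recs(rows)
    segs = movement_segments(recs)
    # oracle: all consecutive day-ordered pairs per individual with the bound
    expected = 0
    for rid, grp in recs.groupby("ring_id"):
        g = grp.sort_values("day")
        for a, b in zip(g.itertuples(), list(g.itertuples())[1:]):
            disp = max(abs(b.lat - a.lat), abs(b.lon - a.lon))
            if 1 < disp < 8:
                expected += 1
    assert len(segs) == expected
    assert (segs["from_day"] <= segs["to_day"]).all()
    disp = np.maximum(segs["dlat"].abs(), segs["dlon"].abs())
    assert ((disp > 1) & (disp < 8)).all()
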