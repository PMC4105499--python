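"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from migwave.cumulate import autocovariate, cumulative_series
from migwave.grid import assign_cells, british_isles_grid, build_cell_table, \
    eligible_cells, queen_adjacency
from migwave.records import annotate_days
from migwave.simulate import WaveParams, simulate_recoveries


def prepared_sim(seed=0, intensity=100, lat_range=(50.0, 56.0),
                 lon_range=(-6.25, 1.25), **wave_kwargs):
    """Simulate a spring wave over the British-Isles lattice and run the
    front of the pipeline; returns a dict of the intermediate objects."""
    grid = british_isles_grid()
    params = WaveParams(seed=seed, intensity=intensity, **wave_kwargs)
    recs, truth = simulate_recoveries(grid, params, lat_range=lat_range,
                                      lon_range=lon_range)
    frame = annotate_days(recs)
    assigned, n_dropped = assign_cells(frame, grid)
    table = build_cell_table(assigned, grid)
    elig = eligible_cells(table)
    adjacency = queen_adjacency(table)
    series = cumulative_series(assigned, elig)
    series = autocovariate(series, adjacency)
    return {"grid": grid, "params": params, "records": recs, "truth": truth,
            "assigned": assigned, "table": table, "eligible": elig,
            "adjacency": adjacency, "series": series}


@pytest.fixture(scope="session")
def bi_sim():
    """Moderate British-Isles-like wave shared by several test modules."""
    return prepared_sim(seed=42, intensity=120)


@pytest.fixture(scope="session")
def bi_fit(bi_sim):
    from migwave.model import fit_car_binomial

    return fit_car_binomial(bi_sim["series"])


@pytest.fixture()
def toy_series():
    """Tiny hand-checkable cumulative series for two adjacent cells."""
    return pd.DataFrame({
        "cell_id": ["A1"] * 4 + ["B1"] * 4,
        "day": [100, 110, 120, 130, 105, 115, 125, 135],
        "n": [1, 2, 3, 4, 3, 6, 9, 12],
        "N": [4, 4, 4, 4, 12, 12, 12, 12],
    }).assign(p=lambda d: d["n"] / d["N"])
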