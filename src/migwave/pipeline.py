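"""End-to-end orchestration from a single config.

A run config (YAML or dict) either points at an encounter CSV or carries a
``simulate`` block, so analyses are reproducible without external data.
``run_progression`` executes filter -> grid -> cumulate -> autocovariate ->
CAR fit -> inversion -> surfaces; ``run_change`` executes per-cell-period
fits -> period autocovariate -> heteroscedastic mixed model -> tests.
The frame-level functions (:func:`prepare_frames`,
:func:`analyze_progression`, :func:`analyze_change`) run the same stages on
in-memory data without touching disk.  Every artifact is written with fixed
float precision so a rerun with the same config and seed reproduces the
bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from migwave import change as _change
from migwave import cumulate as _cumulate
from migwave import grid as _grid
from migwave import maps as _maps
from migwave import model as _model
from migwave import records as _records
from migwave import simulate as _simulate

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.8g"

REGIONS = {
    "british_isles": {
        "grid": _grid.british_isles_grid,
        "belts": _change.british_isles_belts,
        "sim_extent": {"lat_range": (50.0, 59.0), "lon_range": (-10.0, 2.0)},
    },
    "west_europe_nafrica": {
        "grid": _grid.west_europe_nafrica_grid,
        "belts": _change.west_europe_nafrica_belts,
        "sim_extent": {"lat_range": (30.0, 58.0), "lon_range": (-10.0, 22.0)},
    },
}


class PipelineError(RuntimeError):
    """A stage failed; earlier artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything that determines a run's outputs (reproducibility contract)."""

    region: str
    season: str = "spring"
    input: str | None = None
    simulate: dict | None = None
    periods: tuple[tuple[int, int], ...] = ((1908, 1969), (1970, 1990), (1991, 2008))
    percentiles: tuple[float, ...] = _maps.DEFAULT_PERCENTILES
    include_autocov: bool = True
    re_correlation: bool = True
    inversion: str = "plain"  # or "autocov": solve through the gamma*A term
    raster_resolution: float = 0.5
    outdir: str = "migwave_run"
    seed: int = 0

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; "
                             f"valid: {sorted(REGIONS)}")
        if self.season not in ("spring", "autumn"):
            raise ValueError(f"unknown season {self.season!r}")
        if self.input is None and self.simulate is None:
            raise ValueError("config needs either 'input' or a 'simulate' block")
        if self.inversion not in ("plain", "autocov"):
            raise ValueError(f"unknown inversion mode {self.inversion!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "periods" in raw:
            raw["periods"] = tuple(tuple(p) for p in raw["periods"])
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# frame-level analyses (no I/O)

def prepare_frames(frame: pd.DataFrame, region: str, season: str):
    """Filter a raw record frame and build the lattice structures.

    ``frame`` needs columns ring_id, date (ISO), lat, lon and the three
    code columns; day/month/year are derived here.

    Returns (window, grid, assigned, cell_table, eligible_ids, adjacency,
    filter_report).
    """
    window = _records.season_window(region, season)
    grid = REGIONS[region]["grid"]()
    frame = _records.annotate_days(frame)
    filtered, report = _records.filter_frame(frame, window)
    assigned, n_out = _grid.assign_cells(filtered, grid)
    report.n_output -= n_out  # outside-grid records are also unusable
    table = _grid.build_cell_table(assigned, grid)
    elig = _grid.eligible_cells(table)
    adjacency = _grid.queen_adjacency(table)
    return window, grid, assigned, table, elig, adjacency, report


def analyze_progression(
    assigned: pd.DataFrame,
    table: pd.DataFrame,
    elig: set[str],
    adjacency: dict[str, set[str]],
    window=None,
    include_autocov: bool = True,
    re_correlation: bool = True,
    percentiles=_maps.DEFAULT_PERCENTILES,
) -> dict:
    """Cumulate, fit the CAR binomial model and invert to surfaces."""
    series = _cumulate.cumulative_series(assigned, elig)
    series = _cumulate.autocovariate(series, adjacency)
    fit = _model.fit_car_binomial(series, include_autocov=include_autocov,
                                  re_correlation=re_correlation)
    r2 = _model.efron_r2(fit)
    wdays = window.day_range if window is not None else None
    surfaces = pd.concat(
        [_maps.percentile_surface(fit, p, table, window_days=wdays)
         for p in percentiles],
        ignore_index=True)
    return {"series": series, "fit": fit, "pseudo_r2": r2,
            "surfaces": surfaces}


def analyze_change(
    assigned: pd.DataFrame,
    table: pd.DataFrame,
    elig: set[str],
    adjacency: dict[str, set[str]],
    periods: _change.PeriodSpec,
    belts: _change.BeltSpec,
    mc_seed: int = 0,
) -> tuple[pd.DataFrame, _change.ChangeFit]:
    """Median-date table, period autocovariate and the change model."""
    mdt = _change.median_date_table(assigned[assigned["cell_id"].isin(elig)],
                                    table, periods, belts)
    if mdt.empty:
        raise ValueError("no cell-period combination has enough data")
    present = set(mdt.loc[mdt["t0"].notna(), "period"].astype(str))
    missing = [p for p in periods.labels if p not in present]
    if missing:
        raise ValueError(f"period(s) with no usable data: {missing}")
    mdt = _change.period_autocovariate(mdt, adjacency)
    cfit = _change.fit_change_model(mdt, mc_seed=mc_seed)
    return mdt, cfit


# ---------------------------------------------------------------------------
# configured runs with artifacts

def _round_floats(obj, digits=10):
    if isinstance(obj, float):
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, np.floating):
        return _round_floats(float(obj), digits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=2, default=str) + "\n")


def simulate_frames(config: RunConfig, with_periods: bool):
    """Run the generator described by the config's simulate block."""
    region = REGIONS[config.region]
    sim = dict(config.simulate or {})
    extent = {
        "lat_range": tuple(sim.pop("lat_range", region["sim_extent"]["lat_range"])),
        "lon_range": tuple(sim.pop("lon_range", region["sim_extent"]["lon_range"])),
    }
    sim.setdefault("seed", config.seed)
    if "period_shifts" in sim:
        sim["period_shifts"] = {tuple(k) if isinstance(k, (list, tuple)) else k: v
                                for k, v in sim["period_shifts"].items()}
    params = _simulate.WaveParams(**sim)
    periods = _change.PeriodSpec(config.periods) if with_periods else None
    belts = region["belts"]() if with_periods else None
    recs, truth = _simulate.simulate_recoveries(
        region["grid"](), params, periods=periods, belts=belts, **extent)
    return recs, truth, params


def _get_records(config: RunConfig, out: Path, with_periods: bool):
    if config.input is not None:
        recs, rejected = _records.read_records(config.input)
        if len(rejected):
            rejected.to_csv(out / "rejected_rows.csv", index=False)
        return _records.records_to_frame(recs), None
    recs, truth, params = simulate_frames(config, with_periods)
    recs.to_csv(out / "simulated_records.csv", index=False,
                float_format=_FLOAT_FMT)
    truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)
    (out / "simulation_stamp.json").write_text(json.dumps(
        {"seed": params.seed, "params_hash": params.params_hash()}) + "\n")
    return recs, truth


def run_progression(config: RunConfig) -> dict:
    """Fit the CAR binomial model and produce percentile surfaces.

    Writes the artifact bundle (filter report, cell table, design series,
    fit JSON with pseudo-R2, per-cell coefficients, surface CSV, ASCII
    rasters and PNG maps, movement segments) and returns the in-memory
    results alongside the paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_records"
    try:
        frame, truth = _get_records(config, out, with_periods=False)
        stage = "prepare"
        window, grid, assigned, table, elig, adjacency, report = prepare_frames(
            frame, config.region, config.season)
        report.to_json(out / "filter_report.json")
        table.to_csv(out / "cells.csv", index=False, float_format=_FLOAT_FMT)
        stage = "fit"
        res = analyze_progression(assigned, table, elig, adjacency, window,
                                  include_autocov=config.include_autocov,
                                  re_correlation=config.re_correlation,
                                  percentiles=config.percentiles)
        res["series"].to_csv(out / "series.csv", index=False,
                             float_format=_FLOAT_FMT)
        fit = res["fit"]
        summary = fit.summary_dict()
        summary["efron_pseudo_r2"] = res["pseudo_r2"]
        _write_json(summary, out / "fit.json")
        fit.cell_coefs.to_csv(out / "cell_coefs.csv", index=False,
                              float_format=_FLOAT_FMT)
        res["surfaces"].to_csv(out / "surfaces.csv", index=False,
                               float_format=_FLOAT_FMT)
        stage = "raster"
        for p in config.percentiles:
            tag = f"p{int(round(100 * p)):02d}"
            surf = res["surfaces"][res["surfaces"]["p"] == p]
            if surf["date"].notna().sum() >= 3:
                lon_ax, lat_ax, raster = _maps.interpolate_surface(
                    surf, resolution=config.raster_resolution)
                _maps.write_ascii_grid(lon_ax, lat_ax, raster,
                                       out / f"surface_{tag}.asc")
                _maps.plot_surface(lon_ax, lat_ax, raster,
                                   out / f"surface_{tag}.png",
                                   title=f"{int(round(100 * p))}% passage date")
        stage = "segments"
        segs = _maps.movement_segments(assigned)
        segs.to_csv(out / "segments.csv", index=False, float_format=_FLOAT_FMT)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    logger.info("progression run complete: %d cells, pseudo-R2 = %.4f",
                fit.n_cells, res["pseudo_r2"])
    return {"outdir": str(out), "fit": fit, "series": res["series"],
            "surfaces": res["surfaces"], "cells": table,
            "pseudo_r2": res["pseudo_r2"], "truth": truth, "segments": segs,
            "fit_json": str(out / "fit.json"),
            "surfaces_csv": str(out / "surfaces.csv")}


def run_change(config: RunConfig) -> dict:
    """Median-date change analysis across periods and belts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_records"
    try:
        frame, truth = _get_records(config, out, with_periods=True)
        stage = "prepare"
        window, grid, assigned, table, elig, adjacency, report = prepare_frames(
            frame, config.region, config.season)
        report.to_json(out / "filter_report.json")
        table.to_csv(out / "cells.csv", index=False, float_format=_FLOAT_FMT)
        stage = "change_model"
        periods = _change.PeriodSpec(config.periods)
        belts = REGIONS[config.region]["belts"]()
        mdt, cfit = analyze_change(assigned, table, elig, adjacency,
                                   periods, belts, mc_seed=config.seed)
        mdt.to_csv(out / "median_dates.csv", index=False,
                   float_format=_FLOAT_FMT)
        _write_json(cfit.to_json_dict(), out / "tests.json")
        stage = "boxplot"
        _boxplot_t0(mdt, out / "t0_boxplot.png")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    logger.info("change run complete: interaction LRT p = %.4g",
                cfit.lrt["interaction"]["p"])
    return {"outdir": str(out), "median_dates": mdt, "fit": cfit,
            "truth": truth, "tests_json": str(out / "tests.json")}


def _boxplot_t0(mdt: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = mdt.dropna(subset=["t0"])
    belts = [b for b in df["belt"].cat.categories] if hasattr(df["belt"], "cat") \
        else sorted(df["belt"].unique())
    periods = [p for p in df["period"].cat.categories] if hasattr(df["period"], "cat") \
        else sorted(df["period"].unique())
    fig, axes = plt.subplots(1, len(belts), figsize=(3.2 * len(belts), 4),
                             sharey=True, squeeze=False)
    for ax, b in zip(axes[0], belts):
        data, ns = [], []
        for p in periods:
            v = df.loc[(df["belt"] == b) & (df["period"] == p), "t0"]
            data.append(v.to_numpy())
            ns.append(len(v))
        ax.boxplot([d if len(d) else [np.nan] for d in data], whis=(2.5, 97.5))
        ax.set_xticklabels([f"{p}\n(n={n})" for p, n in zip(periods, ns)],
                           fontsize=7)
        ax.set_title(str(b))
    axes[0][0].set_ylabel("median migration date (day of year)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
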