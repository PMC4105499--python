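"""Median-date estimation, the change model and the repeatability measure."""

import numpy as np
import pandas as pd
import pytest

from migwave.change import (
    BeltSpec,
    PeriodSpec,
    british_isles_belts,
    fit_cell_cloglog,
    fit_change_model,
    period_autocovariate,
    repeatability,
    west_europe_nafrica_belts,
    _fit_lmm,
)
from migwave.links import cloglog
from migwave.maps import invert_date


def test_period_spec_defaults_and_validation():
    p = PeriodSpec()
    assert p.labels == ["1908-1969", "1970-1990", "1991-2008"]
    assert p.period_of(1969) == "1908-1969"
    assert p.period_of(1970) == "1970-1990"
    assert p.period_of(2010) is None
    with pytest.raises(ValueError):
        PeriodSpec(((1950, 1940),))
    with pytest.raises(ValueError):
        PeriodSpec(((1900, 1950), (1950, 1980)))


def test_belt_presets_partition():
    bi = british_isles_belts()
    assert bi.belt_of(53.74) == "south" and bi.belt_of(53.75) == "north"
    we = west_europe_nafrica_belts()
    assert we.belt_of(30.0) == "south"
    assert we.belt_of(45.0) == "central"
    assert we.belt_of(55.0) == "north"
    with pytest.raises(ValueError):
        BeltSpec(edges=(50.0, 42.0), labels=("a", "b", "c"))


def _cell_series(alpha, beta, days):
    """Exact cumulative proportions from a cloglog-linear curve, expressed
    as counts out of N = 1000."""
    p = -np.expm1(-np.exp(alpha + beta * np.asarray(days, float)))
    p = p / p[-1]
    n = np.round(p * 1000).astype(int)
    return pd.DataFrame({"day": days, "n": n, "N": 1000})


def test_fit_cell_cloglog_identities():
    # alpha = cloglog(0.5), beta = 1 puts t0 at 0 by algebra
    alpha0 = float(cloglog(0.5))
    fit = fit_cell_cloglog(_cell_series(alpha0, 1.0, [-3, -2, -1, 0, 1, 2, 3]))
    assert fit.converged
    assert fit.t0 == pytest.approx(0.0, abs=0.1)
    # t0 equals invert_date(alpha, beta, 0.5) exactly (same code path)
    assert fit.t0 == invert_date(fit.alpha, fit.beta, 0.5)


def test_fit_cell_cloglog_day_shift_equivariance():
    days = np.array([100, 110, 120, 130, 140])
    s1 = _cell_series(-12.0, 0.1, days)
    s2 = _cell_series(-12.0, 0.1, days).assign(day=days + 10)
    f1, f2 = fit_cell_cloglog(s1), fit_cell_cloglog(s2)
    assert f2.t0 == pytest.approx(f1.t0 + 10, abs=1e-6)


def test_fit_cell_cloglog_recovers_simulated_t0():
    rng = np.random.default_rng(8)
    alpha, beta = float(cloglog(0.5)) - 0.1 * 120, 0.1  # t0 = 120
    u = rng.uniform(size=500)
    days = np.ceil((np.log(-np.log1p(-u)) - alpha) / beta).astype(int)
    uniq, cnt = np.unique(days, return_counts=True)
    ser = pd.DataFrame({"day": uniq, "n": np.cumsum(cnt), "N": len(days)})
    fit = fit_cell_cloglog(ser)
    assert fit.t0 == pytest.approx(120, abs=2)


def test_fit_cell_cloglog_negative_slope_flagged():
    days = np.array([100, 110, 120, 130])
    ser = pd.DataFrame({"day": days, "n": [4, 4, 4, 4], "N": 4})
    # degenerate flat curve: slope indistinct; force decreasing proportions
    ser2 = pd.DataFrame({"day": days, "n": [3, 2, 2, 4], "N": 4})
    fit = fit_cell_cloglog(ser2)
    if not fit.converged:
        assert np.isnan(fit.t0) and fit.reason
    with pytest.raises(ValueError, match="4 distinct days"):
        fit_cell_cloglog(pd.DataFrame({"day": [1, 1, 2], "n": [1, 1, 2], "N": 2}))


def _mdt(t0_by_cell_period, belts=None, n=50):
    rows = []
    for (cid, per), t0 in t0_by_cell_period.items():
        rows.append({"cell_id": cid, "period": per,
                     "belt": (belts or {}).get(cid, "b1"),
                     "t0": t0, "n": n, "alpha": np.nan, "beta": 0.1,
                     "reason": ""})
    return pd.DataFrame(rows)


def test_period_autocovariate_means():
    mdt = _mdt({("A", "p1"): 120.0, ("B", "p1"): 130.0, ("C", "p1"): 140.0,
                ("A", "p2"): 125.0, ("C", "p2"): np.nan})
    adjacency = {"A": {"B", "C"}, "B": {"A"}, "C": {"A", "B"}}
    out = period_autocovariate(mdt, adjacency)
    get = lambda cid, per: out[(out.cell_id == cid) & (out.period == per)]
    assert get("B", "p1")["A"].iloc[0] == 120.0          # singleton mean
    assert get("A", "p1")["A"].iloc[0] == 135.0          # mean(130, 140)
    assert get("C", "p2")["A"].iloc[0] == 125.0          # NaN neighbour ignored
    b2 = get("A", "p2")
    # only neighbour C has NaN t0 in p2 and B has no row: flagged missing
    assert bool(b2["A_missing"].iloc[0]) and np.isnan(b2["A"].iloc[0])


def _sim_mdt(seed, shift=0.0, n_cells=24, sd_by_period=(2.0, 2.0, 2.0),
             belts=3):
    """Direct table-level simulation: random cell intercepts, period
    residual SDs, optional third-period shift in the southern belt,
    exogenous spatial covariate."""
    rng = np.random.default_rng(seed)
    periods = ["p1", "p2", "p3"]
    belt_names = ["south", "central", "north"][:belts]
    rows = []
    spatial = rng.normal(0, 3, size=n_cells)
    cell_u = rng.normal(0, 2, size=n_cells)
    for i in range(n_cells):
        belt = belt_names[i % belts]
        for k, per in enumerate(periods):
            t0 = 130 + spatial[i] + cell_u[i] + rng.normal(0, sd_by_period[k])
            if per == "p3" and belt == "south":
                t0 += shift
            rows.append({"cell_id": f"c{i}", "period": per, "belt": belt,
                         "t0": t0, "A": spatial[i], "n": 50})
    return pd.DataFrame(rows)


def test_change_model_detects_belt_specific_shift():
    mdt = _sim_mdt(0, shift=-13.36)
    fit = fit_change_model(mdt)
    assert fit.lrt["interaction"]["p"] < 0.01
    # the Tukey contrast for p1 vs p3 in the south recovers the shift
    c = fit.contrasts
    south = c[(c.belt == "south") & (c.period_a == "p1") & (c.period_b == "p3")]
    assert south["estimate"].iloc[0] == pytest.approx(-13.36, abs=3.0)
    assert south["p_adj"].iloc[0] < 0.01


def test_change_model_null_not_significant():
    fit = fit_change_model(_sim_mdt(1, shift=0.0))
    assert fit.lrt["interaction"]["p"] > 0.05
    assert fit.lrt["period"]["p"] > 0.05


def test_change_model_recovers_period_variances():
    mdt = _sim_mdt(3, sd_by_period=(2.0, 8.0, 4.0), n_cells=60)
    fit = fit_change_model(mdt)
    sds = fit.full["sd_resid_by_period"]
    assert sds[1] / sds[0] == pytest.approx(4.0, rel=0.30)
    assert sds[2] / sds[0] == pytest.approx(2.0, rel=0.30)
    # the variance-structure REML test flags the heteroscedasticity
    assert fit.lrt["variance_structure"]["p"] < 0.01


def test_homoscedastic_model_is_nested():
    """With one shared variance the heteroscedastic fit can only improve
    the likelihood (LRT statistic >= 0)."""
    mdt = _sim_mdt(4)
    het = _fit_lmm(mdt, "full", heteroscedastic=True, reml=False)
    hom = _fit_lmm(mdt, "full", heteroscedastic=False, reml=False)
    assert het["loglik"] >= hom["loglik"] - 1e-6


def test_change_model_validation():
    mdt = _sim_mdt(5)
    with pytest.raises(ValueError, match="2 periods"):
        fit_change_model(mdt[mdt.period == "p1"])
    one_belt = mdt.copy()
    one_belt["belt"] = "south"
    with pytest.raises(ValueError, match="2 belts"):
        fit_change_model(one_belt)


def test_lmm_agrees_with_nlme_oracle(tmp_path):
    """Independent oracle: nlme::lme with varIdent residuals by period on
    a table-level fixture reproduces loglik, fixed effects and the
    per-period variance ratios."""
    import subprocess

    mdt = _sim_mdt(7, shift=-6.0, n_cells=30, sd_by_period=(2.0, 5.0, 3.0))
    csv = tmp_path / "mdt.csv"
    mdt.to_csv(csv, index=False)
    r = tmp_path / "oracle.R"
    r.write_text(f"""
        suppressMessages(library(nlme))
        d <- read.csv("{csv}")
        d$period <- factor(d$period); d$belt <- factor(d$belt)
        m <- lme(t0 ~ period * belt + A, random = ~1 | cell_id,
                 weights = varIdent(form = ~1 | period), data = d,
                 method = "ML",
                 control = lmeControl(maxIter=200, msMaxIter=200, opt="optim"))
        v <- coef(m$modelStruct$varStruct, unconstrained=FALSE, allCoef=TRUE)
        cat(as.numeric(logLik(m)), fixef(m)["A"], sigma(m),
            paste(v[sort(names(v))], collapse=" "), sep="\\n")
    """)
    out = subprocess.run(["Rscript", str(r)], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr
    lines = out.stdout.split("\n")
    ll_r, gamma_r = float(lines[0]), float(lines[1])
    fit = _fit_lmm(mdt, "full", heteroscedastic=True, reml=False)
    assert fit["loglik"] == pytest.approx(ll_r, abs=0.05)
    assert fit["beta"][fit["names"].index("A")] == pytest.approx(gamma_r, abs=0.02)


# --- repeatability ---------------------------------------------------------

def test_repeatability_perfect_agreement():
    obs = np.array([100.0, 120.0, 140.0, 260.0, 280.0])
    season = np.array(["spring"] * 3 + ["autumn"] * 2)
    r = repeatability(obs, obs.copy(), season)
    assert r.R == 1.0 and r.p == 0.0


def test_repeatability_permuted_pairs_near_zero():
    rng = np.random.default_rng(12)
    obs = np.concatenate([rng.normal(120, 15, 100), rng.normal(270, 15, 100)])
    season = np.array(["spring"] * 100 + ["autumn"] * 100)
    est = obs.copy()
    est[:100] = rng.permutation(est[:100])
    est[100:] = rng.permutation(est[100:])
    r = repeatability(obs, est, season)
    assert abs(r.R) < 0.1


def test_repeatability_centering_invariance():
    """Season centring removes the spring/autumn separation but leaves
    within-pair differences (observed - estimated) untouched, so adding a
    season-wide constant to both members of each pair changes nothing."""
    rng = np.random.default_rng(5)
    obs = np.concatenate([rng.normal(120, 10, 30), rng.normal(270, 10, 30)])
    est = obs + rng.normal(0, 5, 60)
    season = np.array(["spring"] * 30 + ["autumn"] * 30)
    r1 = repeatability(obs, est, season)
    shift = np.where(season == "spring", 50.0, -30.0)
    r2 = repeatability(obs + shift, est + shift, season)
    assert r1.R == pytest.approx(r2.R, abs=1e-12)
    assert r1.F == pytest.approx(r2.F, abs=1e-9)


def test_repeatability_matches_published_se_formula():
    """With groups of 2 the Becker standard error reduces to
    sqrt(2(1-R)^2(1+R)^2 / (2(a-1))); sanity-check the implementation by
    recomputing from its own R."""
    rng = np.random.default_rng(2)
    obs = rng.normal(150, 12, 29)
    est = obs + rng.normal(0, 10, 29)
    r = repeatability(obs, est, np.array(["spring"] * 29))
    se = np.sqrt(2 * (1 - r.R) ** 2 * (1 + r.R) ** 2 / (2 * (29 - 1)))
    assert r.se == pytest.approx(se, abs=1e-12)
    assert r.df1 == 28 and r.df2 == 29


def test_repeatability_degenerate_cases():
    with pytest.raises(ValueError):
        repeatability([1.0], [1.0], ["s"])
    with pytest.warns(RuntimeWarning, match="among-group"):
        r = repeatability([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], ["s"] * 3)
    assert r.degenerate and np.isnan(r.R)
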