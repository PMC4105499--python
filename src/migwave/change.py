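"""Temporal change in migration phenology and the repeatability validation.

The data span is cut into three historical periods (1908-1969, 1970-1990,
1991-2008 by default) and each region into latitudinal belts.  Within each
cell and period a plain binomial cloglog regression of the cumulative
proportion on day gives the median migration date

    t0 = (cloglog(0.5) - alpha) / beta.

Per-cell-period medians are then analysed with a linear mixed model:
t0 ~ period + belt + period:belt + autocovariate, random intercept by cell,
with the residual variance allowed to differ by period (the variance of
median dates differs widely between periods).  Fixed effects are tested by
likelihood-ratio comparisons of nested ML fits; period contrasts within
belts use single-step (Tukey-style) max-|z| adjustment.

The repeatability operation validates model-estimated phenology against
independently observed dates: values are centred by season common means
(so the trivial spring/autumn difference cannot inflate agreement), then an
ANOVA-based intraclass correlation across observed/estimated pairs is
computed with its standard error and F test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from migwave.maps import invert_date

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# periods and belts

@dataclass(frozen=True)
class PeriodSpec:
    """Disjoint, ordered year intervals (bounds inclusive)."""

    intervals: tuple[tuple[int, int], ...] = ((1908, 1969), (1970, 1990), (1991, 2008))

    def __post_init__(self):
        iv = self.intervals
        for (a, b) in iv:
            if a > b:
                raise ValueError(f"bad interval {(a, b)}")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if b1 >= a2:
                raise ValueError("intervals must be disjoint and ordered")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.intervals]

    def period_of(self, year: int) -> str | None:
        for (a, b), lab in zip(self.intervals, self.labels):
            if a <= year <= b:
                return lab
        return None


@dataclass(frozen=True)
class BeltSpec:
    """Latitudinal belts: interior edges (deg N, ascending) and labels
    from south to north; a cell belongs to the belt containing its centre
    latitude (edges belong to the belt above)."""

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need one more label than interior edges")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("edges must be ascending")

    def belt_of(self, lat: float) -> str:
        i = int(np.searchsorted(np.asarray(self.edges), lat, side="right"))
        return self.labels[i]


def british_isles_belts() -> BeltSpec:
    """Two belts split at 53 deg 45 min N."""
    return BeltSpec(edges=(53.75,), labels=("south", "north"))


def west_europe_nafrica_belts() -> BeltSpec:
    """Southern (<42 N), central (42-50 N) and northern (>50 N) Europe."""
    return BeltSpec(edges=(42.0, 50.0), labels=("south", "central", "north"))


# ---------------------------------------------------------------------------
# per-cell-period cloglog fits

@dataclass(frozen=True)
class CellFit:
    alpha: float
    beta: float
    t0: float
    converged: bool
    reason: str = ""


def fit_cell_cloglog(cell_series: pd.DataFrame) -> CellFit:
    """Plain binomial cloglog regression for one cell (and period).

    ``cell_series`` has columns ``day``, ``n`` (cumulative count), ``N``
    (total) — no random effects, no autocovariate.  Returns the intercept,
    slope and median migration date t0; a non-converged fit or a
    non-positive slope yields a missing t0 with the reason recorded.
    """
    import statsmodels.api as sm

    if cell_series["day"].nunique() < 4:
        raise ValueError("need >= 4 distinct days to interpolate a cloglog curve")
    day = cell_series["day"].to_numpy(float)
    y = cell_series["n"].to_numpy(float)
    N = cell_series["N"].to_numpy(float)
    X = np.column_stack([np.ones_like(day), day])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(np.column_stack([y, N - y]), X,
                         family=sm.families.Binomial(
                             link=sm.families.links.CLogLog())).fit(maxiter=200)
        except Exception as exc:  # perfectly degenerate inputs
            return CellFit(np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
    if not res.converged:
        return CellFit(np.nan, np.nan, np.nan, False, "non-convergence")
    alpha, beta = (float(v) for v in res.params)
    if beta <= 0:
        return CellFit(alpha, beta, np.nan, False, "non-positive slope")
    return CellFit(alpha, beta, invert_date(alpha, beta, 0.5), True)


def _cumulate_one(days: np.ndarray) -> pd.DataFrame:
    u, c = np.unique(days, return_counts=True)
    n = np.cumsum(c)
    return pd.DataFrame({"day": u, "n": n, "N": n[-1]})


def median_date_table(
    assigned: pd.DataFrame,
    cells: pd.DataFrame,
    periods: PeriodSpec,
    belts: BeltSpec,
    min_distinct_dates: int = 4,
) -> pd.DataFrame:
    """Per-cell, per-period median migration dates.

    Parameters
    ----------
    assigned
        Window-filtered records with ``cell_id``, ``day``, ``year``.
    cells
        Cell table (for centre latitudes -> belts).
    periods, belts
        Historical periods and latitudinal belts.

    Returns one row per (cell, period) with enough data: columns
    ``cell_id, period, belt, alpha, beta, t0, n, reason`` (t0 is NaN where
    the fit failed or the slope was non-positive).
    """
    lat = dict(zip(cells["cell_id"], cells["center_lat"]))
    rows = []
    df = assigned.copy()
    df["period"] = [periods.period_of(int(y)) for y in df["year"]]
    df = df.dropna(subset=["period"])
    for (cid, per), grp in df.groupby(["cell_id", "period"]):
        if cid not in lat:
            continue
        days = grp["day"].to_numpy(int)
        if len(np.unique(days)) < min_distinct_dates:
            continue
        fit = fit_cell_cloglog(_cumulate_one(days))
        rows.append({
            "cell_id": cid, "period": per, "belt": belts.belt_of(lat[cid]),
            "alpha": fit.alpha, "beta": fit.beta, "t0": fit.t0,
            "n": len(grp), "reason": fit.reason,
        })
    out = pd.DataFrame(rows, columns=["cell_id", "period", "belt", "alpha",
                                      "beta", "t0", "n", "reason"])
    # keep period ordering for the model's factor coding
    out["period"] = pd.Categorical(out["period"], categories=periods.labels,
                                   ordered=True)
    out["belt"] = pd.Categorical(out["belt"], categories=belts.labels,
                                 ordered=True)
    return out.sort_values(["cell_id", "period"]).reset_index(drop=True)


def period_autocovariate(
    table: pd.DataFrame,
    adjacency: dict[str, set[str]],
    weighted: bool = False,
) -> pd.DataFrame:
    """Spatial autocovariate for the change model: per cell and period,
    the mean median migration date of the queen neighbours in that period.

    The paper-style default is the unweighted mean; ``weighted=True``
    switches to record-count weights, mirroring the binomial autocovariate.
    Rows whose neighbours carry no finite t0 in the period get NaN and an
    ``A_missing`` flag.
    """
    out = table.copy()
    out["A"] = np.nan
    out["A_missing"] = True
    lookup = {(r.cell_id, r.period): (r.t0, r.n) for r in table.itertuples()}
    for i, r in out.iterrows():
        vals, wts = [], []
        for k in adjacency.get(r["cell_id"], ()):
            t0n = lookup.get((k, r["period"]))
            if t0n is not None and np.isfinite(t0n[0]):
                vals.append(t0n[0])
                wts.append(t0n[1] if weighted else 1.0)
        if vals:
            out.at[i, "A"] = float(np.average(vals, weights=wts))
            out.at[i, "A_missing"] = False
    return out


# ---------------------------------------------------------------------------
# heteroscedastic linear mixed model on median dates

def _design(df: pd.DataFrame, terms: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix for the requested fixed-effect terms.

    ``terms`` is one of "full" (period*belt + A), "additive"
    (period + belt + A), "no_period" (belt + A), "no_belt" (period + A).
    """
    per = pd.Categorical(df["period"])
    bel = pd.Categorical(df["belt"])
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    p_d = {lv: (per == lv).astype(float) for lv in per.categories[1:]}
    b_d = {lv: (bel == lv).astype(float) for lv in bel.categories[1:]}
    if terms in ("full", "additive", "no_belt"):
        for lv, v in p_d.items():
            cols.append(np.asarray(v))
            names.append(f"period[{lv}]")
    if terms in ("full", "additive", "no_period"):
        for lv, v in b_d.items():
            cols.append(np.asarray(v))
            names.append(f"belt[{lv}]")
    if terms == "full":
        for pl, pv in p_d.items():
            for bl, bv in b_d.items():
                cols.append(np.asarray(pv) * np.asarray(bv))
                names.append(f"period[{pl}]:belt[{bl}]")
    cols.append(df["A"].to_numpy(float))
    names.append("A")
    return np.column_stack(cols), names


def _lmm_loglik(theta, y, X, per, starts, n_periods, heteroscedastic, reml):
    """Profiled (GLS) log-likelihood of the random-intercept LMM with
    per-period residual variances; theta = (log sd_cell, log sd_res...).

    Rows are sorted by cell; ``starts`` are the reduceat segment offsets.
    Uses the Woodbury identity for the rank-1 random-intercept blocks,
    vectorised over cells.
    """
    s_u2 = np.exp(2.0 * theta[0])
    if heteroscedastic:
        s_e2 = np.exp(2.0 * np.asarray(theta[1:1 + n_periods]))
    else:
        s_e2 = np.repeat(np.exp(2.0 * theta[1]), n_periods)
    w = 1.0 / s_e2[per]                      # per-row 1/d
    Sw = np.add.reduceat(w, starts)          # per-cell sum of 1/d
    c = s_u2 / (1.0 + s_u2 * Sw)             # Woodbury rank-1 factor
    WX = w[:, None] * X
    wy = w * y
    swx = np.add.reduceat(WX, starts, axis=0)   # K x p
    swy = np.add.reduceat(wy, starts)
    XtVX = X.T @ WX - (c[:, None] * swx).T @ swx
    XtVy = X.T @ wy - swx.T @ (c * swy)
    ytVy = y @ wy - c @ (swy * swy)
    logdet = float(np.sum(np.log(s_e2[per])) + np.sum(np.log1p(s_u2 * Sw)))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    rss = ytVy - XtVy @ beta
    ll = -0.5 * (len(y) * np.log(2 * np.pi) + logdet + rss)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf, None, None
        ll += 0.5 * XtVX.shape[0] * np.log(2 * np.pi) - 0.5 * ld
    return float(ll), beta, XtVX


def _fit_lmm(df: pd.DataFrame, terms: str, heteroscedastic: bool = True,
             reml: bool = False, warm_start=None) -> dict:
    df = df.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    X, names = _design(df, terms)
    y = df["t0"].to_numpy(float)
    per = pd.Categorical(df["period"]).codes.astype(int)
    n_periods = int(per.max()) + 1
    cell_codes = pd.Categorical(df["cell_id"]).codes
    starts = np.searchsorted(cell_codes, np.arange(cell_codes.max() + 1))
    nvar = 1 + (n_periods if heteroscedastic else 1)

    # moment-based starting values from an OLS variance decomposition:
    # within-cell residual spread by period, between-cell spread of the
    # cell-mean residuals
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta_ols
    counts = np.diff(np.append(starts, len(y)))
    cell_mean_r = np.add.reduceat(r, starts) / counts
    within = r - np.repeat(cell_mean_r, counts)
    sd_u0 = max(float(np.std(cell_mean_r)), 1e-2)
    sd_w = np.array([max(float(np.std(within[per == k])), 1e-2)
                     for k in range(n_periods)])
    resid_sd = max(float(np.std(y)), 1e-3)

    def make_theta(sd_u, sds):
        if heteroscedastic:
            return np.concatenate([[np.log(sd_u)], np.log(sds)])
        return np.array([np.log(sd_u), np.log(np.mean(sds))])

    theta_starts = [
        make_theta(sd_u0, sd_w),
        make_theta(resid_sd / 2.0, np.full(n_periods, resid_sd)),
        make_theta(max(sd_u0 / 10, 1e-3), sd_w),
    ]
    if warm_start is not None and len(warm_start) == nvar:
        theta_starts.insert(0, np.asarray(warm_start, dtype=float))

    def nll(theta):
        ll, _, _ = _lmm_loglik(theta, y, X, per, starts, n_periods,
                               heteroscedastic, reml)
        return -ll if np.isfinite(ll) else 1e12

    res = None
    for theta0 in theta_starts:
        cand = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                 bounds=[(-12, 12)] * nvar,
                                 options={"maxiter": 500, "ftol": 1e-12})
        if res is None or cand.fun < res.fun - 1e-9:
            res = cand
    ll, beta, XtVX = _lmm_loglik(res.x, y, X, per, starts, n_periods,
                                 heteroscedastic, reml)
    if beta is None or not np.isfinite(ll):
        raise RuntimeError(
            "singular change-model fit; consider pooling periods or belts")
    cov = np.linalg.pinv(XtVX)
    sd_cell = float(np.exp(res.x[0]))
    if heteroscedastic:
        sd_res = [float(np.exp(v)) for v in res.x[1:1 + n_periods]]
    else:
        sd_res = [float(np.exp(res.x[1]))] * n_periods
    return {"terms": terms, "loglik": float(ll), "beta": beta, "names": names,
            "cov": cov, "sd_cell": sd_cell, "sd_resid_by_period": sd_res,
            "reml": reml, "heteroscedastic": heteroscedastic,
            "n_params_fixed": X.shape[1], "converged": bool(res.success),
            "theta": [float(v) for v in res.x]}


def _max_abs_z_pvalues(z: np.ndarray, corr: np.ndarray, seed: int = 0,
                       n_mc: int = 200_000) -> np.ndarray:
    """Single-step adjusted p-values for a family of correlated z tests:
    p_i = P(max_k |Z_k| >= |z_i|) under Z ~ N(0, corr).  Seeded Monte
    Carlo, deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    dim = len(z)
    # contrast families are rank-deficient (pairwise differences), so use
    # an eigendecomposition square root rather than Cholesky
    vals, vecs = np.linalg.eigh(corr)
    L = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    draws = L @ rng.standard_normal((dim, n_mc))
    maxabs = np.abs(draws).max(axis=0)
    return np.array([(maxabs >= abs(zi)).mean() for zi in z])


@dataclass
class ChangeFit:
    """Heteroscedastic LMM of median migration dates with nested-model
    likelihood-ratio tests and Tukey-style period contrasts."""

    full: dict
    lrt: dict
    contrasts: pd.DataFrame
    belt_contrasts: pd.DataFrame
    n_used: int
    n_dropped: int
    models: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "fixed_effects": dict(zip(self.full["names"],
                                      [float(v) for v in self.full["beta"]])),
            "sd_cell": self.full["sd_cell"],
            "sd_resid_by_period": self.full["sd_resid_by_period"],
            "loglik": self.full["loglik"],
            "lrt": self.lrt,
            "contrasts": self.contrasts.to_dict(orient="records"),
            "belt_contrasts": self.belt_contrasts.to_dict(orient="records"),
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
        }


def fit_change_model(
    table: pd.DataFrame,
    heteroscedastic: bool = True,
    missing_autocov: str = "drop",
    mc_seed: int = 0,
) -> ChangeFit:
    """Test for change in median migration dates across periods and belts.

    Parameters
    ----------
    table
        MedianDateTable with ``A`` filled (see
        :func:`period_autocovariate`).
    heteroscedastic
        Allow a separate residual variance per period (default; the
        homoscedastic variant is used for the variance-structure test).
    missing_autocov
        "drop" rows with missing autocovariate (default) or "mean"-impute.

    Returns a :class:`ChangeFit` with ML likelihood-ratio tests for the
    period:belt interaction and the period and belt main effects, REML
    test of the per-period variance structure, and single-step adjusted
    pairwise period contrasts within each belt.
    """
    df = table.dropna(subset=["t0"]).copy()
    if missing_autocov == "mean":
        df["A"] = df["A"].fillna(df["A"].mean())
    df = df.dropna(subset=["A"])
    n_dropped = len(table) - len(df)
    df["period"] = pd.Categorical(df["period"])
    df["belt"] = pd.Categorical(df["belt"])
    df["period"] = df["period"].cat.remove_unused_categories()
    df["belt"] = df["belt"].cat.remove_unused_categories()
    periods = list(df["period"].cat.categories)
    belts = list(df["belt"].cat.categories)
    if len(periods) < 2 or len(belts) < 2:
        raise ValueError("need >= 2 periods and >= 2 belts with data")
    counts = df.groupby("period", observed=False).size()
    if (counts == 0).any():
        raise ValueError(f"period(s) without data: {list(counts[counts == 0].index)}")

    # ML fits for fixed-effect LRTs (nested fits warm-started from the
    # richer model's variance parameters)
    full = _fit_lmm(df, "full", heteroscedastic, reml=False)
    add = _fit_lmm(df, "additive", heteroscedastic, reml=False,
                   warm_start=full["theta"])
    no_per = _fit_lmm(df, "no_period", heteroscedastic, reml=False,
                      warm_start=add["theta"])
    no_bel = _fit_lmm(df, "no_belt", heteroscedastic, reml=False,
                      warm_start=add["theta"])

    def lrt(big, small, df_diff):
        chi2 = max(0.0, 2.0 * (big["loglik"] - small["loglik"]))
        return {"chi2": chi2, "df": df_diff,
                "p": float(stats.chi2.sf(chi2, df_diff))}

    P, B = len(periods), len(belts)
    tests = {
        "interaction": lrt(full, add, (P - 1) * (B - 1)),
        "period": lrt(add, no_per, P - 1),
        "belt": lrt(add, no_bel, B - 1),
    }
    if heteroscedastic:
        het_reml = _fit_lmm(df, "full", True, reml=True,
                            warm_start=full["theta"])
        hom_reml = _fit_lmm(df, "full", False, reml=True)
        tests["variance_structure"] = lrt(het_reml, hom_reml, P - 1)

    # Tukey-style period contrasts within belts, from the full model
    names = full["names"]
    beta = full["beta"]
    cov = full["cov"]
    A_bar = float(df["A"].mean())

    def design_row(period, belt):
        row = np.zeros(len(names))
        row[names.index("(Intercept)")] = 1.0
        pn = f"period[{period}]"
        bn = f"belt[{belt}]"
        if pn in names:
            row[names.index(pn)] = 1.0
        if bn in names:
            row[names.index(bn)] = 1.0
        ib = f"period[{period}]:belt[{belt}]"
        if ib in names:
            row[names.index(ib)] = 1.0
        row[names.index("A")] = A_bar
        return row

    rows, C = [], []
    for b in belts:
        for i in range(P):
            for j in range(i + 1, P):
                c = design_row(periods[j], b) - design_row(periods[i], b)
                C.append(c)
                rows.append({"belt": b, "period_a": periods[i],
                             "period_b": periods[j]})
    C = np.asarray(C)
    est = C @ beta
    V = C @ cov @ C.T
    var = np.diag(V).copy()
    valid = var > 0
    se = np.full(len(est), np.nan)
    se[valid] = np.sqrt(var[valid])
    z = est / se
    p_adj = np.full(len(est), np.nan)
    if valid.any():
        Vv = V[np.ix_(valid, valid)]
        sev = se[valid]
        p_adj[valid] = _max_abs_z_pvalues(z[valid], Vv / np.outer(sev, sev),
                                          seed=mc_seed)
    contrasts = pd.DataFrame(rows)
    contrasts["estimate"] = est
    contrasts["se"] = se
    contrasts["z"] = z
    contrasts["p_adj"] = p_adj

    # belt main-effect contrasts (averaged over periods), second family
    rows_b, Cb = [], []
    for i in range(B):
        for j in range(i + 1, B):
            c = np.mean([design_row(p, belts[j]) - design_row(p, belts[i])
                         for p in periods], axis=0)
            Cb.append(c)
            rows_b.append({"belt_a": belts[i], "belt_b": belts[j]})
    Cb = np.asarray(Cb)
    est_b = Cb @ beta
    Vb = Cb @ cov @ Cb.T
    var_b = np.diag(Vb).copy()
    valid_b = var_b > 0
    se_b = np.full(len(est_b), np.nan)
    se_b[valid_b] = np.sqrt(var_b[valid_b])
    z_b = est_b / se_b
    p_b = np.full(len(est_b), np.nan)
    if valid_b.sum() > 1:
        Vv = Vb[np.ix_(valid_b, valid_b)]
        sev = se_b[valid_b]
        p_b[valid_b] = _max_abs_z_pvalues(z_b[valid_b],
                                          Vv / np.outer(sev, sev),
                                          seed=mc_seed)
    elif valid_b.any():
        p_b[valid_b] = 2 * stats.norm.sf(np.abs(z_b[valid_b]))
    belt_contrasts = pd.DataFrame(rows_b)
    belt_contrasts["estimate"] = est_b
    belt_contrasts["se"] = se_b
    belt_contrasts["z"] = z_b
    belt_contrasts["p_adj"] = p_b

    return ChangeFit(full=full, lrt=tests, contrasts=contrasts,
                     belt_contrasts=belt_contrasts, n_used=len(df),
                     n_dropped=n_dropped,
                     models={"additive": add, "no_period": no_per,
                             "no_belt": no_bel})


# ---------------------------------------------------------------------------
# repeatability

@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    se: float
    F: float
    df1: int
    df2: int
    p: float
    n_groups: int
    n0: float
    degenerate: bool = False


def repeatability(observed, estimated, season) -> RepeatabilityResult:
    """ANOVA-based repeatability of observed vs model-estimated dates.

    Each (observed, estimated) pair is one group; values are first centred
    by subtracting, per season, the common mean of all observed AND
    estimated values for that season — removing the trivial spring/autumn
    separation before pooling seasons.  Then

        R = s2_A / (s2_A + s2),  s2_A = (MS_among - MS_within) / n0,

    with the unequal-group-size correction for n0 (groups of size 2 here,
    so n0 = 2), the Becker standard error, and the one-way ANOVA F test.

    An among-group mean square of zero (all pairs identical to each other)
    leaves R undefined; the result is returned flagged ``degenerate``.
    """
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    season = np.asarray(season)
    if obs.shape != est.shape or obs.shape != season.shape:
        raise ValueError("observed, estimated and season must have equal length")
    a = len(obs)
    if a < 2:
        raise ValueError("need at least 2 observed/estimated pairs")

    obs_c = obs.copy()
    est_c = est.copy()
    for s in np.unique(season):
        m = season == s
        common = np.concatenate([obs[m], est[m]]).mean()
        obs_c[m] -= common
        est_c[m] -= common

    data = np.stack([obs_c, est_c], axis=1)  # groups of size 2
    n_tot = 2 * a
    grand = data.mean()
    group_means = data.mean(axis=1)
    ss_among = 2.0 * np.sum((group_means - grand) ** 2)
    ss_within = np.sum((data - group_means[:, None]) ** 2)
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_tot - a)
    n0 = (n_tot - (a * 4) / n_tot) / (a - 1)  # = 2 for equal groups of 2

    if ms_among == 0:
        warnings.warn("repeatability undefined: no among-group variance",
                      RuntimeWarning, stacklevel=2)
        return RepeatabilityResult(np.nan, np.nan, 0.0, a - 1, n_tot - a, 1.0,
                                   a, n0, degenerate=True)
    if ms_within == 0:
        return RepeatabilityResult(1.0, 0.0, np.inf, a - 1, n_tot - a, 0.0,
                                   a, n0)
    s2_a = (ms_among - ms_within) / n0
    R = s2_a / (s2_a + ms_within)
    se = float(np.sqrt(2.0 * (1.0 - R) ** 2 * (1.0 + (n0 - 1.0) * R) ** 2
                       / (n0 * (n0 - 1.0) * (a - 1.0))))
    F = ms_among / ms_within
    p = float(stats.f.sf(F, a - 1, n_tot - a))
    return RepeatabilityResult(float(R), se, float(F), a - 1, n_tot - a, p, a, n0)
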