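"""Conditional-autoregressive binomial mixed model on the cloglog scale.

The model for the cumulative proportion of migrants past cell j by day t is

    cloglog(p_jt) = (alpha + a_j) + (beta + b_j) * t + gamma * A_jt,

with per-cell random intercept and slope (a_j, b_j) ~ N(0, Sigma) (2x2, the
intercept-slope correlation estimated by default) and A_jt the count-weighted
neighbourhood autocovariate.  The response is supplied per row as
(successes n_jt, failures N_j - n_jt), so the binomial likelihood weights
cells by their totals.

Fitting maximises the Laplace approximation to the marginal likelihood:
random effects are independent across cells, so the inner mode-finding
factorises into per-cell 2-d Newton problems, vectorised over cells; the
outer optimisation over fixed effects and variance parameters uses L-BFGS-B.
The day covariate is centred and scaled internally and every reported
quantity is back-transformed to the natural day scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from migwave.links import cloglog_inv, logit_inv

logger = logging.getLogger(__name__)

_INNER_TOL = 1e-10
_INNER_MAXIT = 100
_ETA_CLIP = 30.0
_P_EPS = np.finfo(float).eps


class ConvergenceError(RuntimeError):
    """Raised instead of silently returning an unconverged fit."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CarFit:
    """Fitted CAR binomial mixed model (natural day scale).

    ``re`` holds the per-cell random-effect modes (a_j, b_j);
    ``cell_coefs`` the composed per-cell intercepts and slopes
    alpha_j = alpha + a_j, beta_j = beta + b_j used by the inversion.
    """

    alpha: float
    beta: float
    gamma: float | None
    sd_intercept: float
    sd_slope: float
    corr: float
    re: pd.DataFrame
    cell_coefs: pd.DataFrame
    fitted: pd.DataFrame
    converged: bool
    loglik: float
    link: str
    n_cells: int
    n_rows: int
    optimizer: dict = field(default_factory=dict)

    def coef_for(self, cell_id: str) -> tuple[float, float]:
        row = self.cell_coefs.loc[self.cell_coefs["cell_id"] == cell_id]
        if row.empty:
            raise KeyError(f"cell {cell_id!r} not in fit")
        return float(row["alpha_j"].iloc[0]), float(row["beta_j"].iloc[0])

    def summary_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "sd_intercept": self.sd_intercept,
            "sd_slope": self.sd_slope,
            "corr_intercept_slope": self.corr,
            "loglik": self.loglik,
            "link": self.link,
            "n_cells": self.n_cells,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "optimizer": self.optimizer,
        }


def _binom_eta_derivs(eta, y, size, link):
    """Row loglik, first and second derivatives w.r.t. the linear predictor."""
    if link == "cloglog":
        lam = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        p = -np.expm1(-lam)
        p = np.clip(p, 1e-300, 1.0)
        e = np.exp(-lam)
        mfail = size - y
        ll = y * np.log(p) - mfail * lam
        r = lam * e / p  # lam*exp(-lam)/p, -> 1 as lam -> 0
        g = y * r - mfail * lam
        # d/deta [lam e / p] = (lam e (1-lam) p - (lam e)^2) / p^2
        h = y * (r * (1.0 - lam) - r * r) - mfail * lam
        return ll, g, h
    if link == "logit":
        p = logit_inv(eta)
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
        ll = y * np.log(p) + (size - y) * np.log1p(-p)
        g = y - size * p
        h = -size * p * (1.0 - p)
        return ll, g, h
    raise ValueError(f"unknown link {link!r}")


class _LaplaceProblem:
    """Grouped design for the per-cell Laplace approximation."""

    def __init__(self, series: pd.DataFrame, include_autocov: bool, link: str):
        df = series.sort_values(["cell_id", "day"], kind="mergesort").reset_index(drop=True)
        self.cells = df["cell_id"].unique()
        self.K = len(self.cells)
        code = pd.Categorical(df["cell_id"], categories=self.cells).codes
        self.g = np.asarray(code, dtype=int)
        # reduceat segment starts (rows are sorted by cell)
        self.starts = np.searchsorted(self.g, np.arange(self.K))
        self.day = df["day"].to_numpy(float)
        self.m = float(self.day.mean())
        self.s = float(self.day.std()) or 1.0
        self.tc = (self.day - self.m) / self.s
        self.y = df["n"].to_numpy(float)
        self.size = df["N"].to_numpy(float)
        self.include_autocov = include_autocov
        self.A = df["A"].to_numpy(float) if include_autocov else np.zeros(len(df))
        self.link = link
        self.df = df
        self.const = float(np.sum(
            gammaln(self.size + 1) - gammaln(self.y + 1) - gammaln(self.size - self.y + 1)
        ))
        self.u = np.zeros((self.K, 2))  # warm-started random-effect modes

    def _eta(self, fixed, u):
        a0, b0, gam = fixed
        return (a0 + u[self.g, 0]) + (b0 + u[self.g, 1]) * self.tc + gam * self.A

    def _cell_sums(self, x):
        return np.add.reduceat(x, self.starts)

    def _pen_loglik_cells(self, fixed, u, P):
        ll, _, _ = _binom_eta_derivs(self._eta(fixed, u), self.y, self.size, self.link)
        quad = np.einsum("ki,ij,kj->k", u, P, u)
        return self._cell_sums(ll) - 0.5 * quad

    def inner_newton(self, fixed, P):
        """Per-cell posterior modes of (a_j, b_j), vectorised across cells."""
        u = self.u.copy()
        pen = self._pen_loglik_cells(fixed, u, P)
        converged = False
        for _ in range(_INNER_MAXIT):
            _, gr, hr = _binom_eta_derivs(self._eta(fixed, u), self.y, self.size, self.link)
            G = np.stack([self._cell_sums(gr), self._cell_sums(gr * self.tc)], axis=1)
            G -= u @ P
            H11 = -self._cell_sums(hr) + P[0, 0]
            H12 = -self._cell_sums(hr * self.tc) + P[0, 1]
            H22 = -self._cell_sums(hr * self.tc * self.tc) + P[1, 1]
            det = H11 * H22 - H12 * H12
            det = np.where(det <= 0, np.nan, det)
            step = np.stack([
                (H22 * G[:, 0] - H12 * G[:, 1]) / det,
                (H11 * G[:, 1] - H12 * G[:, 0]) / det,
            ], axis=1)
            step = np.nan_to_num(step, nan=0.0)
            # step halving per cell until the penalised loglik does not drop
            scale = np.ones(self.K)
            for _ in range(20):
                u_new = u + scale[:, None] * step
                pen_new = self._pen_loglik_cells(fixed, u_new, P)
                bad = pen_new < pen - 1e-12
                if not bad.any():
                    break
                scale[bad] *= 0.5
            u = u + scale[:, None] * step
            pen = self._pen_loglik_cells(fixed, u, P)
            if np.max(np.abs(scale[:, None] * step)) < _INNER_TOL:
                converged = True
                break
        self.u = u
        return u, converged

    def laplace_loglik(self, fixed, Sigma):
        """Laplace-approximate marginal log-likelihood."""
        sign, logdet_S = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return -np.inf, None
        P = np.linalg.inv(Sigma)
        u, _ = self.inner_newton(fixed, P)
        ll, _, hr = _binom_eta_derivs(self._eta(fixed, u), self.y, self.size, self.link)
        H11 = -self._cell_sums(hr) + P[0, 0]
        H12 = -self._cell_sums(hr * self.tc) + P[0, 1]
        H22 = -self._cell_sums(hr * self.tc * self.tc) + P[1, 1]
        det = H11 * H22 - H12 * H12
        if np.any(det <= 0):
            return -np.inf, u
        quad = np.einsum("ki,ij,kj->k", u, P, u)
        per_cell = self._cell_sums(ll) - 0.5 * quad - 0.5 * logdet_S - 0.5 * np.log(det)
        return float(per_cell.sum()) + self.const, u


def _theta_unpack(theta, include_autocov, re_correlation):
    i = 0
    a0 = theta[i]; i += 1
    b0 = theta[i]; i += 1
    gam = 0.0
    if include_autocov:
        gam = theta[i]; i += 1
    sa = np.exp(theta[i]); i += 1
    sb = np.exp(theta[i]); i += 1
    rho = np.tanh(theta[i]) if re_correlation else 0.0
    Sigma = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
    return (a0, b0, gam), Sigma


def _glm_start(prob: _LaplaceProblem):
    """Fixed-effect starting values from an ordinary binomial GLM."""
    import statsmodels.api as sm

    X = [np.ones(len(prob.tc)), prob.tc]
    if prob.include_autocov:
        X.append(prob.A)
    X = np.column_stack(X)
    endog = np.column_stack([prob.y, prob.size - prob.y])
    link = sm.families.links.CLogLog() if prob.link == "cloglog" else sm.families.links.Logit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, X, family=sm.families.Binomial(link=link)).fit()
    return np.asarray(res.params, dtype=float)


def fit_car_binomial(
    series: pd.DataFrame,
    include_autocov: bool = True,
    re_correlation: bool = True,
    link: str = "cloglog",
) -> CarFit:
    """Fit the CAR binomial mixed model to a cumulative series.

    Parameters
    ----------
    series
        Design table from :func:`migwave.cumulate.autocovariate` (or
        :func:`~migwave.cumulate.cumulative_series` when
        ``include_autocov=False``): one row per (cell, observed day) with
        columns ``cell_id, day, n, N`` and ``A`` if the autocovariate is
        used.
    include_autocov
        Include the neighbourhood autocovariate as a global fixed effect.
    re_correlation
        Estimate the random intercept-slope correlation (default); set
        False to force independence, which can stabilise small fits.
    link
        "cloglog" (default) or "logit" for comparison.

    Raises
    ------
    ValueError
        Fewer than 2 cells (random effects unidentifiable) or a cell with
        fewer than 4 rows.
    ConvergenceError
        The optimiser failed; diagnostics attached.
    """
    if include_autocov and "A" not in series.columns:
        raise ValueError("series has no autocovariate column 'A'; "
                         "run cumulate.autocovariate or set include_autocov=False")
    prob = _LaplaceProblem(series, include_autocov, link)
    if prob.K < 2:
        raise ValueError("at least 2 cells required (random effects unidentifiable)")
    rows_per_cell = np.diff(np.append(prob.starts, len(prob.y)))
    if rows_per_cell.min() < 4:
        raise ValueError("every cell needs >= 4 rows (distinct days)")

    fixed0 = _glm_start(prob)
    theta0 = list(fixed0) + [np.log(0.3), np.log(0.3)]
    if re_correlation:
        theta0.append(0.0)
    theta0 = np.asarray(theta0, dtype=float)
    nfix = len(fixed0)
    bounds = [(None, None)] * nfix + [(-10.0, 4.0), (-10.0, 4.0)]
    if re_correlation:
        bounds.append((-4.0, 4.0))

    def nll(theta):
        fixed, Sigma = _theta_unpack(theta, include_autocov, re_correlation)
        ll, _ = prob.laplace_loglik(fixed, Sigma)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7,
                                     "eps": 1e-6})
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-8,
                                          "fatol": 1e-9})
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun):
        raise ConvergenceError("CAR binomial GLMM did not converge",
                               {"message": str(res.message), "theta": list(res.x)})
    if not res.success:
        raise ConvergenceError(
            f"CAR binomial GLMM optimiser reported failure: {res.message}",
            {"theta": list(res.x), "nll": float(res.fun)})

    fixed, Sigma = _theta_unpack(res.x, include_autocov, re_correlation)
    ll, u = prob.laplace_loglik(fixed, Sigma)
    a0, b0, gam = fixed

    # back-transform from the centred/scaled day to the natural scale:
    # eta = (a0 - b0*m/s) + (b0/s)*day  and per-cell likewise
    m, s = prob.m, prob.s
    alpha = a0 - b0 * m / s
    beta = b0 / s
    a_nat = u[:, 0] - u[:, 1] * m / s
    b_nat = u[:, 1] / s
    M = np.array([[1.0, -m / s], [0.0, 1.0 / s]])
    Sig_nat = M @ Sigma @ M.T
    sd_a = float(np.sqrt(Sig_nat[0, 0]))
    sd_b = float(np.sqrt(Sig_nat[1, 1]))
    corr = float(Sig_nat[0, 1] / (sd_a * sd_b)) if sd_a > 0 and sd_b > 0 else 0.0

    sa_std = float(np.sqrt(Sigma[0, 0]))
    sb_std = float(np.sqrt(Sigma[1, 1]))
    big = (np.abs(u[:, 0]) > 6 * max(sa_std, 1e-8)) | (np.abs(u[:, 1]) > 6 * max(sb_std, 1e-8))
    for cid in prob.cells[big]:
        warnings.warn(f"possible separation / extreme random effect in cell {cid}",
                      RuntimeWarning, stacklevel=2)

    eta_hat = prob._eta(fixed, u)
    inv = cloglog_inv if link == "cloglog" else logit_inv
    p_hat = np.clip(inv(eta_hat), _P_EPS, 1.0 - _P_EPS)
    fitted = prob.df.copy()
    fitted["p_hat"] = p_hat

    re = pd.DataFrame({"cell_id": prob.cells, "a_j": a_nat, "b_j": b_nat})
    cell_coefs = pd.DataFrame({
        "cell_id": prob.cells,
        "alpha_j": alpha + a_nat,
        "beta_j": beta + b_nat,
    })
    return CarFit(
        alpha=float(alpha), beta=float(beta),
        gamma=float(gam) if include_autocov else None,
        sd_intercept=sd_a, sd_slope=sd_b, corr=corr,
        re=re, cell_coefs=cell_coefs, fitted=fitted,
        converged=True, loglik=float(ll), link=link,
        n_cells=prob.K, n_rows=len(prob.y),
        optimizer={"method": "L-BFGS-B + Laplace", "nll": float(res.fun),
                   "n_iter": int(res.get("nit", -1)) if hasattr(res, "get") else -1,
                   "day_center": m, "day_scale": s},
    )


def predict_proportion(fit: CarFit, cell_id: str, t, A=None):
    """Predicted cumulative proportion in a cell at day t.

    The autocovariate term enters only when the caller supplies ``A`` (the
    inversion to percentile dates uses the cell intercept and slope alone).
    """
    aj, bj = fit.coef_for(cell_id)
    eta = aj + bj * np.asarray(t, dtype=float)
    if A is not None:
        if fit.gamma is None:
            raise ValueError("fit has no autocovariate coefficient")
        eta = eta + fit.gamma * np.asarray(A, dtype=float)
    inv = cloglog_inv if fit.link == "cloglog" else logit_inv
    out = inv(eta)
    return float(out) if np.ndim(out) == 0 else out


def efron_r2(fit: CarFit, series: pd.DataFrame | None = None) -> float:
    """Efron pseudo-R2: squared correlation of observed and fitted
    cumulative proportions over all (cell, day) rows.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    df = fit.fitted if series is None else series.merge(
        fit.fitted[["cell_id", "day", "p_hat"]], on=["cell_id", "day"])
    p = df["p"].to_numpy(float)
    ph = df["p_hat"].to_numpy(float)
    if np.std(p) == 0 or np.std(ph) == 0:
        warnings.warn("Efron pseudo-R2 undefined: zero variance", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(p, ph)[0, 1] ** 2)
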