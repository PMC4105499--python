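"""The CAR binomial mixed model: links, fitting, predictions, pseudo-R2."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from migwave.links import cloglog, cloglog_inv, logit, logit_inv
from migwave.model import (
    CarFit,
    ConvergenceError,
    efron_r2,
    fit_car_binomial,
    predict_proportion,
)
from tests.conftest import prepared_sim


def test_cloglog_round_trip():
    p = np.arange(0.01, 1.0, 0.01)
    assert np.allclose(cloglog_inv(cloglog(p)), p, atol=1e-12)
    assert np.allclose(logit_inv(logit(p)), p, atol=1e-12)
    # strictly increasing
    assert (np.diff(cloglog(p)) > 0).all()


def test_cloglog_vs_logit_shape():
    """cloglog is the asymmetric sigmoid: at eta = 0 it gives 1 - 1/e,
    not 1/2."""
    assert cloglog_inv(0.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)
    assert logit_inv(0.0) == pytest.approx(0.5)


def test_predict_proportion_closed_forms(bi_fit):
    cid = bi_fit.cell_coefs["cell_id"].iloc[0]
    aj, bj = bi_fit.coef_for(cid)
    t_at_zero = -aj / bj  # eta = 0 there
    assert predict_proportion(bi_fit, cid, t_at_zero) == pytest.approx(
        1 - np.exp(-1), abs=1e-9)
    assert predict_proportion(bi_fit, cid, -1e6) == pytest.approx(0.0, abs=1e-12)
    assert predict_proportion(bi_fit, cid, 1e6) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(KeyError):
        predict_proportion(bi_fit, "nonexistent", 100.0)


def test_fit_requires_multiple_cells(toy_series):
    single = toy_series[toy_series.cell_id == "A1"]
    with pytest.raises(ValueError, match="2 cells"):
        fit_car_binomial(single, include_autocov=False)


def test_fit_requires_autocov_column(toy_series):
    with pytest.raises(ValueError, match="autocovariate"):
        fit_car_binomial(toy_series, include_autocov=True)


def test_fit_recovers_generating_fixed_effects():
    """Data simulated from the model itself (no spatial trend, gamma = 0):
    the fitted fixed effects sit near the generating values and the
    fitted random-effect modes are centred."""
    sim = prepared_sim(seed=7, intensity=200, speed=0.0,
                       cell_sd_intercept=2.0, cell_sd_slope=0.005,
                       gamma_spatial=0.0)
    fit = fit_car_binomial(sim["series"], include_autocov=False)
    truth = sim["truth"]
    assert fit.beta == pytest.approx(truth["beta"].mean(), rel=0.08)
    assert fit.alpha == pytest.approx(truth["alpha"].mean(), rel=0.08)
    assert abs(fit.re["a_j"].mean()) < 0.3
    assert abs(fit.re["b_j"].mean()) < 0.01
    assert ((fit.fitted["p_hat"] > 0) & (fit.fitted["p_hat"] < 1)).all()


def test_link_choice_changes_loglik(bi_sim):
    """Refitting the same series with a logistic instead of cloglog link
    gives a different likelihood: the link is not a cosmetic choice."""
    f1 = fit_car_binomial(bi_sim["series"], include_autocov=False)
    f2 = fit_car_binomial(bi_sim["series"], include_autocov=False, link="logit")
    assert abs(f1.loglik - f2.loglik) > 1.0


def test_doubling_counts_keeps_point_estimates():
    """Doubling every (n, N-n) pair doubles the information but not the
    location of the optimum: the binomial weighting contract."""
    sim = prepared_sim(seed=11, intensity=150, speed=0.0,
                       cell_sd_intercept=1.0, cell_sd_slope=0.003,
                       gamma_spatial=0.0, lat_range=(50.0, 53.0),
                       lon_range=(-4.75, 1.25))
    series = sim["series"]
    doubled = series.assign(n=series["n"] * 2, N=series["N"] * 2,
                            p=series["p"])
    f1 = fit_car_binomial(series, include_autocov=False)
    f2 = fit_car_binomial(doubled, include_autocov=False)
    assert f2.alpha == pytest.approx(f1.alpha, rel=0.02)
    assert f2.beta == pytest.approx(f1.beta, rel=0.02)


def test_efron_r2_trivials(bi_fit):
    obs = bi_fit.fitted["p"].to_numpy()
    perfect = bi_fit.fitted.assign(p_hat=obs)
    fit = CarFit(**{**bi_fit.__dict__, "fitted": perfect})
    assert efron_r2(fit) == pytest.approx(1.0)
    anti = bi_fit.fitted.assign(p_hat=1 - obs)
    fit = CarFit(**{**bi_fit.__dict__, "fitted": anti})
    assert efron_r2(fit) == pytest.approx(1.0)  # squared correlation


def test_efron_r2_independent_predictions_near_zero(bi_fit):
    rng = np.random.default_rng(0)
    shuffled = bi_fit.fitted.assign(
        p_hat=rng.permutation(bi_fit.fitted["p_hat"].to_numpy()))
    fit = CarFit(**{**bi_fit.__dict__, "fitted": shuffled})
    assert efron_r2(fit) < 0.05


def test_efron_r2_zero_variance_flagged(bi_fit):
    flat = bi_fit.fitted.assign(p_hat=0.5)
    fit = CarFit(**{**bi_fit.__dict__, "fitted": flat})
    with pytest.warns(RuntimeWarning, match="zero variance"):
        assert np.isnan(efron_r2(fit))


def test_efron_r2_high_on_model_faithful_data(bi_fit):
    """On data generated exactly cloglog-linear per cell the model
    interpolates the observed proportions almost perfectly."""
    assert efron_r2(bi_fit) > 0.98


def test_laplace_fit_agrees_with_lme4_oracle(tmp_path):
    """Independent oracle: lme4::glmer (Laplace, cloglog, random
    intercept+slope) on a small fixture reproduces our fixed effects and
    log-likelihood."""
    sim = prepared_sim(seed=5, intensity=80, cell_sd_intercept=2.0,
                       cell_sd_slope=0.008, gamma_spatial=0.0,
                       lat_range=(50.0, 54.4), lon_range=(-6.25, -0.1))
    series = sim["series"]
    fit = fit_car_binomial(series, include_autocov=False)
    csv = tmp_path / "series.csv"
    series.to_csv(csv, index=False)
    rscript = tmp_path / "oracle.R"
    rscript.write_text(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$fail <- d$N - d$n
        d$dayc <- scale(d$day)
        m <- glmer(cbind(n, fail) ~ dayc + (dayc | cell_id), data=d,
                   family=binomial(link="cloglog"))
        fe <- fixef(m)
        ctr <- attr(d$dayc, "scaled:center"); sc <- attr(d$dayc, "scaled:scale")
        cat(fe[1] - fe[2]*ctr/sc, fe[2]/sc, as.numeric(logLik(m)), sep="\\n")
    """)
    out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    alpha_r, beta_r, ll_r = (float(v) for v in out.stdout.split())
    assert fit.alpha == pytest.approx(alpha_r, rel=1e-2)
    assert fit.beta == pytest.approx(beta_r, rel=1e-2)
    # our optimum should be at least as good, and close
    assert fit.loglik >= ll_r - 0.5
    assert fit.loglik == pytest.approx(ll_r, abs=1.0)
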