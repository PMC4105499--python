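"""Link functions shared by the model, the inversion and the simulator.

The complementary log-log link, cloglog(p) = log(-log(1 - p)), maps a
cumulative proportion to a scale on which the arrival curve of a migration
wave is linear in date when per-individual arrival days follow a
minimum-Gumbel law.  The logistic link is provided for comparison; it is a
symmetric sigmoid, whereas the cloglog curve approaches 1 faster than it
leaves 0.

Every module uses these implementations, so the simulator, the fitted model
and the inversion to percentile dates are exact inverses of each other up to
floating-point error.
"""

from __future__ import annotations

import numpy as np

# Probabilities are clamped to the open unit interval before taking logs so
# that observed proportions of exactly 0 or 1 stay finite on the link scale.
_EPS = 1e-12


def cloglog(p):
    """Complementary log-log link: log(-log(1 - p)) for p in (0, 1)."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    return np.log(-np.log1p(-p))


def cloglog_inv(eta):
    """Inverse cloglog: p = 1 - exp(-exp(eta)).

    Computed as -expm1(-exp(eta)), which is accurate for very negative eta
    (small p) where 1 - exp(...) would cancel.
    """
    eta = np.asarray(eta, dtype=float)
    # above ~36.7 exp(eta) overflows while p is already 1 to machine
    # precision, so cap the inner exponent
    return -np.expm1(-np.exp(np.minimum(eta, 50.0)))


def logit(p):
    """Logistic link log(p / (1 - p)), for comparison with cloglog."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    return np.log(p) - np.log1p(-p)


def logit_inv(eta):
    """Inverse logit (standard logistic CDF)."""
    from scipy.special import expit

    return expit(np.asarray(eta, dtype=float))
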