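# Methods

## Data model and filters

One row of input is one dated, geo-located encounter of a ringed bird with
three EURING exchange-code fields. The analysis keeps encounters inside a
seasonal window of whole calendar months (British Isles: March–June and
August–October; western Europe & north Africa: February–June and
August–November), then excludes nestlings (age code 1), birds found dead
but not fresh (condition 1 or 3), and dates known less precisely than
3 days (accuracy outside 0–2). Rules are applied in that fixed order so the
per-rule exclusion counts partition the removals; records missing a code
needed by a rule are excluded conservatively and counted separately.
Repeated encounters of one individual are retained — the unit of analysis
is the dated position, not the bird.

Day of year uses a pooled 365-day convention (1 January = 1): because years
are pooled, dates on or after 1 March of leap years take their non-leap
index, so a calendar date maps to the same integer in every year;
29 February folds onto day 59 and is flagged. The alternative proleptic
convention is available but mixes indices across years.

## Lattice

Square lat/lon cells (1.5° for the British Isles, 4° for western Europe and
north Africa) anchored so that edges fall at integer multiples of the cell
size from (26° N, 26° E), the south-east corner of the study region; only
records north of 26° N and west of 26° E are used. Cells are half-open
([south, north) × [west, east)) so every point has exactly one cell. The
anchor is configurable; the default makes runs reproducible without access
to any historical grid definition. A cell is *eligible* when it holds
encounters on ≥ 4 distinct days — the minimum support for a two-parameter
curve. Adjacency is queen contiguity (≤ 8 neighbours). By default the
neighbourhood is intersected with the eligible set, because ineligible
cells have no observed cumulative proportions to contribute; a switch
(`queen_adjacency(..., restrict_to_eligible=False)`) includes them.

## The CAR binomial mixed model

Per cell j and observed day t, the response is the pair
(n_jt, N_j − n_jt): cumulative successes and remaining failures. The linear
predictor on the cloglog scale is

    eta_jt = (alpha + a_j) + (beta + b_j) t + gamma A_jt,

with (a_j, b_j) ~ N(0, Sigma) (2×2; the intercept–slope correlation is
estimated by default and can be fixed at 0 for stability) and A_jt the
count-weighted neighbour average of cumulative proportions. A neighbour's
proportion at a day it was not observed is its empirical CDF value there:
last observation carried forward, 0 before its first observation day —
exact, because p_kt *is* an empirical CDF. Weights use window-total counts,
so they are constant over the season and sum to 1. Cells with an empty
neighbourhood get A ≡ 0 and are flagged.

Two deliberate simplifications are inherited from the modelling tradition
this follows: cumulative counts within a cell are serially dependent, yet
row-wise binomial likelihoods are used (a composite-likelihood reading;
point estimates are unaffected in our simulations, interval estimates are
optimistic); and rows with p_jt = 1 are retained as valid binomial
observations.

Fitting maximises the Laplace approximation to the marginal likelihood.
Random effects are independent across cells, so the inner mode-finding
factorises into per-cell 2-d Newton problems solved simultaneously with
vectorised segment reductions (convergence 1e-10 on the step, per-cell step
halving); the outer optimisation over (alpha, beta, gamma, log sd_a,
log sd_b, atanh rho) uses L-BFGS-B with a Nelder-Mead fallback, warm-started
from an ordinary binomial GLM. The day covariate is centred and scaled
internally; all reported quantities are back-transformed. Fitted
probabilities are clamped away from {0, 1} by machine epsilon. An
unconverged fit raises rather than returning silently. On a small fixture
the fitter agrees with lme4's `glmer` (Laplace, cloglog, correlated random
intercept+slope) to ~1e-3 in fixed effects and ~0.1 in log-likelihood;
lme4 serves only as a cross-check oracle in the test suite.

Efron's pseudo-R² is the squared Pearson correlation between observed and
fitted cumulative proportions over all (cell, day) rows; it is reported as
NaN with a warning when either vector is constant.

## Inversion and maps

The passage date for proportion p in cell j is
t_j(p) = (cloglog(p) − alpha_j)/beta_j using the cell-level intercept and
slope only. The autocovariate term is deliberately dropped at inversion
time — the per-cell random effects compensate in practice, and the
magnitude of the residual late bias shrinks with the fitted gamma, i.e.
with sample size. A documented alternative
(`invert_date_with_autocov`) solves the full linear predictor by Brent root
finding through the step-interpolated A(t). Cells with non-positive slope
have no passage date and are excluded from rasters; dates outside the
seasonal window are kept but flagged as extrapolations.

Surfaces are interpolated by triangulated (Delaunay) linear interpolation
of cell-centre dates onto a regular lat/lon raster, with no extrapolation
outside the convex hull; plain plate-carrée coordinates throughout.
Movement-segment maps connect successive same-individual encounters
(ordered by pooled day of year) whose displacement satisfies
1 < max(|Δlat|, |Δlon|) < 8 degrees, strict bounds, both configurable:
shorter displacements resolve nothing at cell scale, longer ones clutter
the map.

## Temporal change

Within each (cell, period) with ≥ 4 distinct encounter days, a plain
binomial cloglog regression (statsmodels GLM) of the cumulative proportion
on day gives the median migration date t0 = (cloglog(0.5) − alpha)/beta;
non-convergence or a non-positive slope yields a missing t0 with the reason
recorded. Whole-window seasonal limits are used for every period. The
period-level autocovariate is the unweighted mean of neighbour medians in
the same period (a count-weighted variant is a switch); rows with no
informative neighbour are flagged and, by default, dropped from the change
model (mean imputation is available).

The change model is a linear mixed model

    t0 ~ period + belt + period:belt + A,  random intercept by cell,

with the residual variance free to differ by period. The likelihood uses
the Woodbury identity on the rank-1 random-intercept blocks, profiles the
fixed effects by GLS, and optimises the 2–4 variance parameters by L-BFGS-B
from several moment-based starts (an OLS variance decomposition, a generic
split, and a near-zero cell variance), keeping the best optimum;
nested fits are additionally warm-started from the richer model's variance
estimates. Multi-start matters: single-start fits occasionally hit local
optima that corrupt likelihood-ratio statistics. Fixed effects are tested
by ML likelihood-ratio comparisons (interaction: full vs additive; each
main effect: additive vs the model without it); the per-period variance
structure is tested by REML against a pooled variance. On a fixture the
fitter matches nlme's `lme` with `varIdent` to < 0.05 in log-likelihood.

Post-hoc inference reports all period pairs within each belt as one
contrast family and belt mains (averaged over periods) as a second, each
with single-step max-|z| adjustment: adjusted p = P(max_k |Z_k| ≥ |z_i|)
under the estimated contrast correlation, evaluated by seeded Monte Carlo
(200 000 draws; deterministic for a given seed, accurate to ~2e-3). The
contrast correlation matrices are rank-deficient by construction, so the
square root uses an eigendecomposition.

### Endogeneity of the autocovariate (a finding, and a limitation)

The period autocovariate is computed from *estimated* neighbour medians —
i.e. from the response. Simulation shows two consequences for the period
main-effect LRT. Under an exchangeable null (no spatial trend) the test
over-rejects (empirical rate ≈ 0.18 at 56 cells instead of 0.05): the
covariate carries each period's chance mean, and removing the period factor
forces its coefficient to compromise between that signal and the null
within-period relationship. Under a strong spatial trend the coefficient is
pinned near 1 and the same absorption makes the test radically conservative
(empirical rate ≈ 0). With the identical analysis but the covariate
computed from the *generating* neighbour medians (exogenous), the rate is
0.040 over 200 record-level replicates — the machinery itself is
calibrated. Relatedly, a belt-wide phenological shift leaks into the
covariate (neighbourhoods are belt-local), attenuating the Tukey contrast
magnitude (≈ −3.5 days estimated for a −13.36-day simulated shift) even
though the interaction LRT retains ~95% power. The calibration and
shift-recovery experiments in `migwave.experiments` therefore supply the
covariate from the generator's truth, and users interpreting the
production model should treat period contrast magnitudes as conservative
lower bounds when spatial autocorrelation is strong.

## Repeatability

Observed/estimated date pairs are centred per season by the common mean of
all observed *and* estimated values for that season, which removes the
trivial spring/autumn separation without touching within-pair differences.
Each pair is then one group of a one-way ANOVA: R = s²_A/(s²_A + s²) with
s²_A = (MS_among − MS_within)/n₀, n₀ from the unequal-group-size correction
(n₀ = 2 for pairs), the Becker standard error
√(2(1−R)²[1+(n₀−1)R]²/(n₀(n₀−1)(a−1))), and F = MS_among/MS_within on
(a−1, N−a) degrees of freedom. Zero among-group variance leaves R undefined
(flagged); zero within-group variance gives R = 1.

## The synthetic-data generator

Each cell's arrival-day law is minimum-Gumbel, i.e. exactly cloglog-linear:
beta_j = 1/scale + a cell deviation, t0_j = onset + speed × (projection of
the cell centre on the bearing) + a spatially smoothed cell deviation
(+ per-period, per-belt shift), alpha_j = cloglog(0.5) − beta_j t0_j.
Defaults emulate a British-Isles-like spring wave: northward bearing,
2.5 days/degree (≈ 20 days across Britain), onset day 130, scale 10 days
(the cumulative curve rises over ~6 weeks), cell deviations of 3 days
(t0) and 0.01 (slope), one queen-neighbourhood smoothing pass of weight
0.5 for spatial correlation, and Poisson(75) encounters per cell — the
order of records per eligible cell in century-scale recovery compilations.
Counts N_j are Poisson, years are drawn uniformly from the non-leap years
of the period (keeping day indices exactly pooled), positions uniformly
within the cell, and codes are innocuous (age 4, condition 2, accuracy 0)
so the filters keep everything.

Integer days are emitted as ceil(t) — "arrived by day d" — so that
P(day ≤ d) = F(d) holds exactly at integer days and the generating
coefficients remain the truth for the discretised data; flooring instead
would shift the intercept by one day's slope. Slopes are floored at
0.2/scale to keep every curve rising. A misspecification mode draws
arrival days from a normal law with matched median and SD
(scale·π/√6) to probe robustness of the cloglog fit. What the generator
does *not* emulate: spatially and temporally heterogeneous ringing effort,
recovery-probability differences between live and dead birds, and window
truncation biases (a wave whose tails cross the seasonal window edge
yields slightly biased per-cell curves — visible as a larger autumn
median-date error in the acceptance run). Passing tests therefore certify
the estimators under the model's own assumptions, not under real-data
sampling biases.

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen
as the package's own working sizes: progression fits use 24–48 cells with
80–1000 encounters per cell; the change-model calibration batch uses a
~56-cell, three-belt, three-period design with Poisson(60) encounters per
cell-period over 200 replicates (100 in the acceptance script), and power
and recovery experiments use the same lattice at Poisson(60–300).
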