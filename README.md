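# migwave

Spatial progression and timing of bird migration estimated from dated,
geo-located encounter records (ring recoveries, ringing data, or sighting
databases), with a temporal-change analysis across historical periods and a
synthetic migration-wave generator for fully reproducible experiments.

## The problem and the model

Ring-recovery archives hold a century of dated encounters of individually
marked birds. Pooling years, the fraction of a migratory population that has
reached or passed a place by day *t* — the *progression* of migration — can
be modelled per grid cell *j* from the cumulative count of encounters
n<sub>jt</sub> out of the cell total N<sub>j</sub>. The cumulative
proportion p<sub>jt</sub> = n<sub>jt</sub>/N<sub>j</sub> is taken linear in
date on the complementary log-log scale,

```
cloglog(p_jt) = (alpha + a_j) + (beta + b_j) * t + gamma * A_jt ,
```

a binomial generalized linear mixed model with cell as a random grouping
factor and date as a random slope, plus a conditional-autoregressive (CAR)
term: the autocovariate A<sub>jt</sub> is the count-weighted average
proportion already past the queen-adjacent cells,
A<sub>jt</sub> = Σ<sub>k∈∂j</sub> w<sub>k</sub> p<sub>kt</sub> with
w<sub>k</sub> = N<sub>k</sub>/N<sub>∂j</sub>. Model quality is summarised by
Efron's pseudo-R², the squared correlation between observed and fitted
proportions.

Inverting each cell's fitted curve gives the *timing* of migration: the day
at which a proportion *p* has passed,

```
t_j(p) = (cloglog(p) - alpha_j) / beta_j ,
```

mapped for p ∈ {5%, 15%, 50%, 85%} and interpolated into isochrone
surfaces. For temporal change, per-cell cloglog fits within historical
periods (1908–1969, 1970–1990, 1991–2008 by default) yield median migration
dates t₀ = t<sub>j</sub>(0.5), which are compared across periods and
latitudinal belts with a linear mixed model (random cell intercept,
per-period residual variances, spatial autocovariate), likelihood-ratio
tests and Tukey-style contrasts. Agreement between model-estimated and
independently observed phenology is quantified by an ANOVA-based
repeatability with season-centred pairs.

Because ring-recovery databanks are access-restricted, the package includes
a first-class generator (`migwave.simulate`) that draws encounter records
from exactly the model's assumptions — per-cell minimum-Gumbel arrival laws
whose medians advance along a directional wavefront — with every generating
coefficient exported, so estimates can be scored against known truth.

## Worked example

`examples/02_progression_surfaces.py` simulates a spring wave over the
British Isles (48 cells, ~300 encounters each), fits the CAR model and
inverts it:

```
48 eligible cells, 2732 (cell, day) rows
fixed effects: alpha = -14.12, beta = 0.0967 per day, autocovariate gamma = 0.122
random-effect SDs: intercept 1.73, slope 0.0113
Efron pseudo-R2 = 0.9989 (squared correlation of observed and fitted proportions)

50% passage dates vs generating truth: mean abs error 0.72 days

south-to-north progression of the fitted median passage date:
  lat 50.75N  day  133.0 (truth  132.3)
  lat 55.25N  day  143.7 (truth  142.7)
  lat 58.25N  day  150.0 (truth  150.1)
```

The slope beta ≈ 0.097/day is the steepness of the cumulative curve (the
generator used 1/scale = 0.1); the fitted median passage climbs ~17 days
from the Channel to northern Scotland, recovering the simulated 2.5
days/degree wavefront. `examples/03_temporal_change.py` adds a 13.36-day
advancement of the southern belt's last period and shows the belt × period
interaction flagged at chi²(4) = 29.5, p = 6e-06, while the period and belt
main effects stay non-significant.

The other examples cover the generator itself (`01_simulate_wave.py`) and
the repeatability validation (`04_repeatability.py`). A thin CLI wraps the
pipeline for config-driven runs:

```
migwave progression config.yaml --seed 1   # fit + surfaces + maps
migwave change config.yaml                 # temporal-change analysis
migwave simulate config.yaml               # records + truth table only
migwave report <bundle-dir>                # summarise an existing run
```

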