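# Methods

`phenofall` analyses the autumn phenology of deciduous broadleaf trees:
when leaves turn color, when they fall, how long the display lasts, how
much total color a canopy produces in a year, and how all of these respond
to climate. This note documents the models, the numerical choices, and the
synthetic data that the test suite exercises.

## From field visits to phenological measures

Field observations are percent estimates per tree and visit date: the
fraction of leaves that have turned color (r_n) and the fraction that have
fallen (j_n). Trees are aggregated to a species-level trajectory as the
unweighted mean over the 3–5 individuals present on each visit date (the
aggregation is a design choice; per-tree thresholds averaged afterwards
would be an alternative and the reader functions keep per-tree series
available).

Assuming percents change linearly between visits, the stage date `c_x`
(coloration) or `f_x` (fall) is the day of year at which the trajectory
first reaches x ∈ {10, 25, 50, 75, 90} percent, interpolated between the
bracketing visits. Two conventions matter:

* **No backward extrapolation.** If the first visit of a year is already at
  or above x, the stage is recorded as missing with an explicit reason.
  Early-coloring species genuinely lose their earliest thresholds this way.
* **First upward crossing.** Observer corrections can make a percent series
  locally non-monotone; the first crossing is used, deterministically.

Derived measures:

* duration `d_x = f_90 − c_x` (days); negative values are flagged as
  anomalies rather than silently dropped;
* amount of color `A`: the time-integral of the per-visit color intensity
  `y_n = r_n · (1 − j_n/100)`, taken as the trapezoidal area under the
  piecewise-linear y curve across the observed visit span. The two-branch
  visit-by-visit area formula that field studies quote is algebraically the
  trapezoid rule; the tests verify the identity on random trajectories.
  Units: 100 units of A = one calendar day with a fully red, fully retained
  canopy. A is integrated only over the observed span — no extrapolation
  beyond the first or last visit.

## Climate predictors

* **Trailing windows.** For every end day (1–365) and window length (1–52
  weeks) the window mean of daily temperature or precipitation is the
  arithmetic mean over `weeks × 7` calendar days ending at and including
  the end day, reaching into the previous calendar year when necessary.
  The inclusive convention shifts results by under one day of data relative
  to the exclusive reading. Day 366 of leap years participates inside
  windows but is folded off the end-day axis so the correlation grids have
  fixed 365×52 shape. Windows tolerate up to 10% missing days (pairwise
  deletion); monthly means use the same tolerance.
* **Monthly means.** Mean temperature and mean daily precipitation for
  May–October give the 12 candidate predictors of the empirical model.
  Precipitation windows and months use means of the daily values, not sums.
* **Daylength.** P(doy) comes from the CBM solar-declination model
  (Forsythe et al. 1995), smooth and annual-periodic, with daylength
  defined by the sun's centre crossing the horizon; a configuration switch
  adds standard atmospheric refraction. The process model uses P only
  through thresholds and ratios, so the variant choice is second-order (the
  tests bound the formula against an independent Spencer-series ephemeris
  at 0.25 h).

## Correlation fingerprints

For each species and measure, the Pearson correlation between the
interannual metric and every trailing window forms a 365×52 map. Cells are
masked at the pointwise two-sided critical value
`r_crit = sqrt(t²/(t² + df))`, df = n − 2 (0.468 at α = 0.05 with 16 df).
Years missing a metric are deleted pairwise, so df adjusts per cell. No
multiple-testing correction is applied — the maps are exploratory, and the
window extrema are reported only among cells with the full year count to
avoid unstable small-n extremes.

## Empirical model: stepwise regression

Each stage (5 coloration + 5 fall levels per species) is regressed
independently on the 12 monthly candidates, bidirectionally from the empty
model: the single candidate with the smallest partial p enters if
p ≤ 0.20, then any retained term with p > 0.05 is purged, iterating to a
fixed point (cycles terminate by state tracking). Selection decisions use
partial F-tests on the SSE change — identical to squared partial t in the
regular case, but well-defined when a fit becomes perfect (σ̂² = 0), where
t-based p-values would spuriously admit every remaining candidate. Ties
break by the fixed candidate order (t_may…t_oct, p_may…p_oct), making the
procedure deterministic. Reported coefficients and p-values come from the
final OLS fit and are cross-checked against statsmodels in the tests.

The liberal entry / strict retention pair admits spurious terms far more
often than 5% per model when fed pure noise — an inherent property of
stepwise search that the tests document, and the reason the candidate set
is limited to monthly leaf-on means.

## Process model: cold-degree-days × photoperiod

State S_sen accumulates daily after D_start, the first post-solstice day
on which the photoperiod drops to P_start. The daily increment for days
*following* D_start is

    R_sen = max(0, T_b − T)^x · f(P)^y,
    f(P) = P / P_start   (variant 1)   or   1 − P / P_start   (variant 2),

with exponents x, y ∈ {0, 1, 2}. A stage occurs on the first day
S_sen ≥ Y_crit, one Y_crit per level, so a five-stage suite carries 9
parameters. x = 0 removes temperature entirely: the photoperiod-only null
repeats the same dates every year. With this accumulation convention a
constant unit rate reaches Y_crit = k exactly k days after D_start.

**Calibration.** The discrete grid P_start ∈ {10, …, 16} h (0.5-h step,
13 values) × T_b ∈ {7, …, 30} °C (0.5° step, 47 values) × x × y × variant
is searched exhaustively (10,998 structures). At each node the five Y_crit
are located by a deterministic 1-D search: the candidate set is the
accumulation value attained on each observed stage date (this set provably
contains a zero-error threshold when the node is the generating one), and
at the winning node a dense pass over every accumulation value within ±10
days of the observations refines each Y_crit. The criterion is the RMSE
pooled over all stage observations with equal weight; stages a candidate
never reaches in some year are penalised at the day after year end, and
ties between nodes resolve to the smallest (P_start, T_b, x, y, variant)
in fixed iteration order. Y_crit is forced non-decreasing in level by a
running-maximum adjustment when noise inverts it (logged). Because only
Y_crit is continuous and its RMSE profile is a step function of the
accumulation values, this candidate search finds the same optimum a
general-purpose 1-D minimiser would, deterministically.

The per-year first-crossing searches are vectorised by shifting each
year's non-decreasing accumulation curve into a disjoint numeric range and
running a single `searchsorted`; a full-grid calibration of one suite takes
a few seconds on one CPU.

Identifiability caveats: at x = 0 every T_b is equivalent, and at y = 0 the
two photoperiod variants coincide, so those coordinates are reported as the
tie-break defaults in null structures. Parameter-recovery tests therefore
draw truths from the identifiable region (x ≥ 1).

## Model comparison and robustness

RMSE, Nash–Sutcliffe model efficiency ME = 1 − Σ(o−p)²/Σ(o−ō)², and
AICc = n ln(sse/n) + 2K + 2K(K+1)/(n−K−1) (Gaussian SSE likelihood up to
constants, which cancel in ΔAIC = AICc(empirical) − AICc(process)). For
the process suite n pools years × observed stages with K = 9; the
empirical suite at comparison level counts all selected coefficients plus
the five intercepts. Cross-validation removes a whole *year* at a time —
all five stages leave the calibration set together — refits both models,
and scores the pooled held-out predictions over exactly n folds.

## Projection and trends

Fitted suites run forward over daily scenario weather (2010–2099 in the
standard setup). Durations and A are not projected directly: percent
trajectories are reconstructed as piecewise-linear curves through the five
projected stage dates, the first segment extrapolated back to 0% and the
last forward to 100%, sampled daily, and fed through the same
amount-of-color integral used on observations (the tests assert this
internal consistency). Rates of change are OLS slopes on calendar year
with t-based 95% confidence intervals — slope uncertainty only, no account
of parameter or structural uncertainty, and no autocorrelation correction.

Because stages are projected independently, crossing-over can occur (a
later threshold before an earlier one, or 90% color after 90% fall). The
consistency checker reports violations per year; trend fits keep flagged
years by default (reconstruction repairs non-monotone date sequences with
a running maximum) rather than excluding species outright — both
behaviours are available to callers.

## Synthetic data: what it emulates and what it does not

The weather generator produces a sinusoidal seasonal cycle (defaults:
7.1 °C annual mean, 13 °C amplitude peaking near day 200 — a cool-temperate
northeastern-US climate with ~1100 mm annual precipitation), AR(1) daily
anomalies (φ = 0.7, marginal SD 3 °C), i.i.d. gamma daily precipitation,
and an optional secular trend. Scenario series ramp the annual mean
linearly so the final-30-year mean exceeds baseline by a prescribed
contrast (presets: +4.9 °C/+170 mm "a1fi-like", +2.4 °C/+140 mm "b1-like").

Phenology truths come from forward runs of the process model with
species-specific parameters spanning early and late coloring, x ∈ {0,1,2}
(one pure photoperiod-null species) and both photoperiod variants; Y_crit
values are placed so climatological stage dates hit realistic targets
(coloration onset late August–early October, fall trailing by 10–14 days).
Two observation-process features matter:

* percent trajectories are sampled every 3–7 days from day 244 with
  truncated-Gaussian percent noise per tree (SD 5 points), clipped and
  re-monotonised — so interpolated dates carry discretisation and noise
  errors like real records, and early thresholds are sometimes missing;
* stage timing carries a late-summer **moisture pathway**: all of a year's
  dates shift together by 2 days per SD of the Aug–Sep precipitation
  anomaly (wetter → later). Field correlation maps show precipitation
  signals of this order, and the cold-degree-day structure deliberately
  omits moisture; without such a pathway the process family would contain
  the generating truth exactly, and the documented robustness contrast
  between the two model families (the empirical fit winning in-sample, the
  process model winning held-out) could not arise in principle.

What the generator does **not** emulate: spatial structure, multi-site
variation, observer drift, logistic (saturating) trajectory shapes by
default (a logistic option exists for robustness checks), gap-filled
weather, or the covariance structure of downscaled GCM output. Passing
tests therefore demonstrate correctness of the algorithms and the claimed
statistical behaviours under these idealised conditions, not validation
against field data.

## Problem sizes used in the automated checks

The suites run at the study's natural scale: 18 years × 8 species, 5
levels × 2 kinds. Full-grid calibrations (10,998 structures) appear in the
recovery checks; the repeated-replicate robustness comparison (100
datasets × 19 fits each) uses a reduced 3×3×3×3×2 grid, which preserves
the comparison while keeping the experiment to a few minutes. Trend
coverage uses 200 seeds; the trapezoid identity, 1,000 random
trajectories.
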