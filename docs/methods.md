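# Methods

## Degree-day exposures

Daily degree days above a threshold `T` use the single-sine
approximation: the diurnal temperature course is one sine wave with mean
`M = (tmax + tmin)/2` and amplitude `W = (tmax - tmin)/2`, and the day's
degree days are the time-averaged exceedance of the curve over `T`
(closed form in `degree_days.daily_dd`).  Each day uses its own tmin/tmax
only; no interpolation toward the next day's minimum is attempted.  The
closed form is pinned against direct numerical integration of the sine
curve (1e-6 over a thousand random triples) in the test suite, so the
formula's semantics are fixed by an independent oracle rather than by
convention.

Season exposures sum daily values over a fixed calendar window, April 1
to September 30 inclusive (the window never contains February, so leap
days are irrelevant).  Degree days are precomputed at the fixed 10 degC
cutoff and every integer threshold from 20 to 43 degC, so the knot search
never returns to the daily data.  County-years with any missing in-season
day are excluded and logged, never imputed: exclusion is conservative and
keeps the exposure totals comparable across rows.

## The estimating equation

The loss-cost ratio (LCR) — indemnities over liability, per county-year —
is regressed on three piecewise-linear exposure bins
(`x1 = dd(10) - dd(c1)`, `x2 = dd(c1) - dd(c2)`, `x3 = dd(c2)`), season
precipitation and its square, county fixed effects, year fixed effects,
and state-specific quadratic time trends.  Conventions:

- Fixed effects enter as explicit dummy columns and the system is solved
  by QR-based least squares: exactness and a transparent covariance over
  speed, which is appropriate at the panel sizes targeted here (10^3-10^4
  rows).  A Frisch-Waugh partialling path is used internally by the knot
  search and is verified against the dummy path in the tests.
- `Time_t` is the year minus the first sample year, so trend columns are
  well conditioned.  The reference state's trend columns are omitted:
  with year dummies present, the full set would be collinear.  Any
  residual collinearity is pruned by pivoted QR on the column-scaled
  design with a logged warning; the five weather columns are never
  pruned (a genuinely degenerate weather column — e.g. no county-day
  above `c2` in a tiny panel — falls back to the minimum-norm solution
  with a warning).
- The regression is unweighted.  A liability-weighted variant would
  answer a different (dollar-weighted) question and is deliberately not
  the default.
- Standard errors are clustered by year: the cluster-sandwich covariance
  with the conventional small-sample factor `G/(G-1) * (n-1)/(n-k)`.
  The bread `(X'X)^-1` is formed from a QR factorization of `X` rather
  than by inverting `X'X`, which matters numerically for dummy-plus-trend
  designs whose squared condition number is large.  The implementation is
  checked in the tests against both a hand-assembled sandwich and
  statsmodels' cluster-robust OLS.
- Inference on averages uses a normal reference; the number of year
  clusters is reported alongside so users with few clusters can apply a
  t reference themselves.

Both the overall R^2 and the within-R^2 (fit of the weather terms after
partialling out all controls) are reported, since either may be the
relevant goodness-of-fit summary depending on the comparison being made.

## Knot search

The lower cutoff is fixed at 10 degC.  The two free knots are selected by
estimating the full equation at every integer pair with `c1` in [20, 35]
and `c2` in [36, 43] (16 x 8 = 128 candidates) and keeping the pair with
maximal R^2 (equivalently minimal SSE); exact ties break toward the
smallest `c1`, then the smallest `c2`.  Integer candidates follow from
the integer-threshold exposure schedule; finer grids can be supplied
through `ModelSpec`.  Each dependent variable — the total LCR and each
cause-specific LCR — gets its own search.  All candidate R^2 values are
retained on the returned fit.  No inference adjustment is made for the
search itself: reported standard errors are conditional on the selected
knots, and users should treat near-ties in the candidate table as a sign
the knot location is weakly identified.

## Warming counterfactual

A uniform `delta` degC scenario adds `delta` to every daily tmin and tmax
and leaves precipitation (and, implicitly, CO2) unchanged.  For each
county the exposure bins are time-averaged over the sample years before
and after the shift, **at the knots of the historical fit** — the knots
are not re-searched under the counterfactual, matching the logic that the
estimated response function is being evaluated at a new exposure level.
The impact is the slope vector dotted with the mean exposure shift; the
cross-county average is unweighted; its standard error comes from the
delta method with the year-clustered slope covariance (the exposure shift
is treated as deterministic).  Cause-specific impacts use each cause's
own fit and knots, so they need not sum to the total-model impact; the
discrepancy is computed and reported rather than hidden.

## Synthetic data generator

The generator exists so that every downstream stage has exact ground
truth.  It emulates:

- **Weather.**  A county-specific seasonal sine (base 13 degC, amplitude
  12.5 degC, peak near day 200) plus a cross-state mean-temperature
  gradient (5 degC span) and i.i.d. county offsets (sd 1 degC); daily
  AR(1) anomalies (rho 0.7, innovation sd 2 degC); a fixed 11 degC
  diurnal range; Bernoulli-gamma rainfall (wet-day probability 0.3,
  gamma shape 0.6, scale 18.6 mm).  These defaults put season degree days
  above 29 degC in the mid-50s (degC day) and season precipitation near
  610 mm — the scale of rain-fed corn counties east of the 100th
  meridian — while leaving days above 38 degC rare, as they are in that
  region.
- **The loss process.**  The latent total LCR is exactly the estimating
  equation: base level 0.14 plus the centered weather terms (true knots
  (29, 38) degC, slopes (-6e-5, 1e-3, 8e-3) LCR per degree day,
  precipitation terms (-4e-4, 3.3e-7) per mm and mm^2), county effects
  (sd 0.015), year effects (sd 0.02), and i.i.d. noise (sd 0.03),
  truncated into [0, 1].  The defaults keep truncation below 1% of draws
  (asserted in the tests), because the estimator is OLS and heavy
  truncation would bias recovery; the truncated share is logged whenever
  it exceeds that.  Weather terms are centered at their sample means so
  the base level is the mean LCR; centering shifts only the intercept and
  never the slopes.  The slope magnitudes imply one extra day at 35 degC
  raises the LCR by roughly 0.01 — a realistic marginal effect for a
  moderate-heat day.
- **The insurance book.**  Liabilities are lognormal around $2M per
  county and constant within county across years, so LCR variation is
  loss-driven.  Three percent of county-years are randomly absent from
  the book, giving an unbalanced panel.  Total losses are allocated to
  causes by softmax weights over standardized weather features — degree
  days above c1 (drought), above c2 (heat), season precipitation (excess
  moisture), cool-season days with tmin below 5 degC (cold) — with
  lognormal allocation noise; cause losses sum to the total exactly by
  construction.  Cold losses are split across their three raw spellings
  (freeze, frost, cold wet weather) so the reader-side taxonomy is
  genuinely exercised.

A `TruthRecord` carries the true coefficients, the realized county/year
effects, the latent and truncated LCR per row, and the analytic per-county
warming impact (the true slope vector dotted with the county's exposure
shift, which is exactly linear in the slopes).

What the generator does **not** emulate, and what passing tests therefore
do not establish about real data: zero inflation of the LCR (most real
county-years have no claims; available via `zero_inflation_prob` but off
by default because it breaks the linear-model correspondence), spatial
correlation of weather across counties (anomalies are independent, so
year-clustered inference is if anything stressed less than in real data
where weather is spatially correlated within years), adjuster
misattribution of causes, LCRs above 1 from over-claims, liability growth
or endogenous insurance participation, and real geography.  Recovery
results here demonstrate the estimator is correct under its own
assumptions, not that those assumptions hold in administrative data.

## Panel construction conventions

Raw cause names are matched case-insensitively; unmapped names collapse
to "other" with a warning, so the mapping is total.  County-years with a
liability record but no loss records are genuine zero-claim observations
and get LCR 0; loss records with no liability row are dropped with a
warning (the ratio is undefined); duplicate liability rows are an error.
LCRs above 1 are scaled back to 1 with the cause components scaled
proportionally, preserving cause-to-total additivity; the count is
logged.  The panel stays unbalanced — no interpolation.

## Robustness designs

The lower-frequency designs are deliberately simple, clearly labelled
stand-in conventions, each exposed through `RobustDesign` so they can be
re-aligned with external specifications:

- `ma5` / `ma10`: trailing (optionally centered) within-county moving
  averages of the dependent variable and every weather regressor, with
  the precipitation square averaged as its own variable; county and year
  fixed effects are kept and errors remain year-clustered.  Overlapping
  windows induce serial correlation that year clustering does not fully
  absorb; treat these SEs as approximate.
- `crosssec`: one row per county of full-sample means; OLS with state
  indicators.
- `longdiff`: per county, the mean of the last five years minus the mean
  of the first five.
- The single-cross-section designs use heteroskedasticity-robust errors,
  HC3 by default: its leverage correction keeps test size honest at
  county-level sample sizes (verified by a pure-noise size check in the
  tests); HC1 is available via `se_type`.

Knots are inherited from the baseline annual fit and never re-searched,
so the designs differ only in the temporal frequency of identifying
variation.

## Problem sizes

The default generator scale is 5 states x 8 counties x 26 years (about a
thousand county-years) — large enough that the knot search and warming
impacts are informative, small enough that the full pipeline runs in
seconds.  Replication-style properties (knot recovery in 18/20 low-noise
draws, 95% CI coverage of every slope in at least 90% of 50 default-noise
draws, warming-impact recovery within two SEs in at least 90% of 50
draws) are verified at 25 states x 8 counties (200 counties) x 26 years,
the package's standing replication scale.

## Known limitations

- OLS on a [0, 1] outcome: no censoring model; the generator keeps
  truncation rare, but with real zero-inflated LCRs the linear model is a
  first-order approximation.
- Post-search inference is conditional on the selected knots.
- Year clustering handles arbitrary within-year cross-county dependence
  but not spatial dependence that persists across years.
- The warming scenario is uniform and holds precipitation and CO2 fixed;
  it is an exposure-shift evaluation of the estimated response, not a
  climate projection.
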