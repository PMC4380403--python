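# Methods

This note records the scientific and numerical choices behind
`dendrofit`: the model and its assumptions, how each pipeline stage is
defined where more than one convention exists, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The growth model

Annual plot-mean basal area increment is modelled multiplicatively,

BAI = MG · f₁(Size) · f₂(Competition) · f₃(Precipitation) · f₄(Temperature) + ε,

with MG the maximum potential growth (mm²/yr) and each modifier a
unit-interval response function.  The multiplicative form encodes two
assumptions: the most limiting factor dominates (a modifier near zero
suppresses growth regardless of the others), and covariate effects
interact — the marginal effect of climate is scaled down under heavy
competition, which is precisely the interaction of interest when
asking whether thinning buffers climate stress.

Six modifier families are implemented, with these parameterisations:

| family | f(x) | roles | constraints |
|---|---|---|---|
| logistic | 1/(1+(x/a)^b) | size, precipitation | a>0 (half-saturation, f(a)=0.5); b<0 increasing |
| modified_gaussian | exp(−½((x−a)/b)²) | competition, temperature | b≠0 |
| negative_exponential | a·e^{bx} | competition | a∈(0,1], b≤0 |
| negative_potential | min(1, a·x^b) | competition | a>0, x≥0.1 (power law diverges at 0) |
| log_normal | exp(−½(ln(x/a)/b)²) | temperature | a>0, x>0 |
| modified_laplace | exp(−b·abs(x−a)) | temperature | b≥0; maximum exactly 1 at x=a |

Each family's admissible parameter space is validated at construction
so that its range stays inside [0, 1] on its domain; wrong-sign shape
parameters (e.g. a positive decay rate in the negative exponential)
are rejected with a diagnostic rather than silently producing values
above 1.

The error is Gamma with shape k ("dispersion") and scale μ/k, so the
mean equals the model prediction and the coefficient of variation is
1/√k, constant across the mean — matching the heteroscedastic,
positively skewed residuals of raw BAI chronologies.  One global k is
fitted per model and counts as a parameter.  Observations must be
strictly positive; a plot-mean BAI of zero (all missing rings) is a
data error, not a floorable value, because it lies outside the Gamma
support.

The competition modifier's intercept may vary by site (parallel
competition curves on otherwise comparable stands, reflecting
unmodelled site quality).  The intercept is fixed at 1 unless a site
effect is declared; declared site intercepts that differ from 1 are
estimated, the reference site's stays fixed, and parameter counts
follow (a two-site model with one free intercept has 10 parameters:
MG, 2 size, 1 free intercept + 1 shared slope, 2 precipitation,
2 temperature, dispersion).

## Estimation

Maximum likelihood by simulated annealing with geometric cooling
(factor 0.9), Gaussian proposals scaled to 10% of each parameter's
bound range, 100 steps per temperature level, the initial temperature
calibrated so that ~80% of initial uphill moves are accepted, and a
stop after 10 levels without improvement or a fixed evaluation budget.
Several independent chains (default 3; the first starts from the
bound-box midpoint, the rest from random feasible points) are run
within the budget and the best polished result is kept.  Each chain's
best point is polished with a bounded Nelder–Mead simplex; the winner
gets one polish restart.

Two likelihood-surface pathologies get dedicated handling, both
deterministic per seed:

* **Peaked-kernel collapse.**  The location of a Laplace (or
  Gaussian/log-normal) kernel has a kinked profile, and when its rate
  parameter drifts to 0 the kernel flattens to the constant 1, hiding
  the location entirely; a simplex started there cannot recover the
  optimum.  After polishing, each peaked kernel's (location, rate)
  plane is scanned on a coarse grid (25 × 7 log-spaced rates) and the
  fit is re-polished from any grid point that improves the likelihood.
* **Monotonicity ridges.**  The template's logistic sign declares the
  response's monotonicity, and the default bounds restrict the shape
  parameter to that sign, removing a mirror-image mode in which a
  decreasing size response trades against other modifiers.

Default bounds are data-driven: MG in (0, 10 × max observed BAI],
location parameters within the observed covariate range (temperature
widened ±5 °C), the Gamma shape in [0.05, 500]; all user-overridable.

Uncertainty is summarised by 2-log-likelihood-unit support intervals
found by bisection along each parameter axis with the other parameters
held at their estimates; when the profile never drops by 2 units
before a bound, the bound is returned and flagged.  Full re-profiling
(re-optimising the other parameters at each probe) is available behind
a flag but is not the default, as it is an order of magnitude slower
and rarely moves the interval on these data.  Degenerate intervals
(steep profiles collapsing onto the estimate) are representable.

Model selection uses AIC = −2LL + 2k with ΔAIC computed against a
designated reference model.  The lowest-AIC model is selected outright
only when it beats the runner-up by ≥ 2 units; otherwise the model
with the fewest parameters among those within 2 units wins.  Models
fitted to different observation counts cannot be compared.

## Chronology and competition construction

Ring widths are converted to BAI inside-out: the cumulative radius at
year t is the pith offset plus summed widths, BAIₜ = π(rₜ² − rₜ₋₁²).
Bark is ignored.  Cores of a tree are averaged per year *after* BAI
conversion; tree series are averaged per plot, and chronology years
are kept only when at least five trees contribute (boundary
inclusive).

The size covariate of year t is the start-of-season diameter,
DBHₜ = 2rₜ₋₁ (cumulative widths *excluding* the ring dated t): the
size in place while ring t forms.  This keeps the covariate
predetermined with respect to the response and makes the ingest-side
reconstruction agree exactly with the forward simulator.

Periodic inventories become annual competition series by linear
interpolation, basal area and density each interpolated independently.
Between two inventories the non-harvest ("natural") change is spread
evenly per year; a thinning's removals enter as a step at the *start*
of the thinning year — thinning from below precedes the growing
season — so that year's covariate reflects post-thinning crowding and
the series still passes through every inventory value exactly.

## Climate

Monthly records are pooled into fixed windows (annual; hydrological
year Oct–Sep; growing season Apr–Sep; spring Mar–May; summer Jun–Aug;
May–July; June–July; autumn Sep–Nov; winter Dec–Feb), precipitation by
summation and temperature variables by arithmetic mean.  A pool value
exists only when every member month is present — no partial sums — so
cross-year pools are absent in the first year of record.  Temperatures
can be transferred between altitudes with a lapse rate of 0.5 °C per
100 m.  Candidate covariates are screened by Kendall tau-b (tie-
corrected, because rounded BAI values tie); screening is advisory and
the fitted covariates remain an explicit configuration choice.  There
is no gap imputation: years with missing pools simply drop out of the
likelihood.

## Projection

Monthly scenario series are bias-adjusted to a site by per-calendar-
month delta change over an observed overlap window (default
2001–2011): additive offsets for temperature, multiplicative factors
for precipitation, with an additive fallback (and warning) when a
month's scenario precipitation is zero over the overlap.

Competition trajectories: heavy thinning holds basal area at its
present level (management maintains it); control lets it grow linearly
at the recently observed rate until a self-thinning asymptote, then
holds it (a smooth saturating alternative is configurable).  Any
constant-diameter projection holds competition constant under both
regimes, isolating the climate signal for a fixed tree size.

Dynamic projections update the diameter each year by the predicted
increment, DBHₜ₊₁ = √(DBHₜ² + 4·BAIₜ/π), so the cumulative predicted
BAI equals π/4·(DBH_T² − DBH₀²) identically.  Years whose covariates
leave the declared calibration ranges are flagged as extrapolated, not
suppressed.  Replicate projections (plots, size classes) are
summarised as mean ± one standard deviation.

Long-term trends are read from a discrete cubic smoothing spline
(second-difference penalty): minimise ‖y − f‖² + λ‖Δ²f‖², whose
frequency response is H(ω) = 1/(1 + λ(2 − 2cos ω)²).  λ is set
analytically from H(2π/30 yr) = ½, i.e. a 50% amplitude cutoff at a
30-year period.  The binding contract is the measured amplitude
response (0.50 at 30 yr, > 0.9 at 100 yr on a 300-point series,
verified by least-squares sinusoid fits), not any particular stiffness
formula; constants pass through unchanged.  Series shorter than half
the cutoff are smoothed lightly with a warning.

## Synthetic data

The generator produces complete study-shaped datasets so every
pipeline stage runs without field data.

*Climate*: monthly normals (a dry-summer regime with wet
winters/springs and a sinusoidal temperature cycle peaking in July)
plus an AR(1) annual anomaly applied to all months of a year —
additive for temperature (default sd 0.8 °C), multiplicative for
precipitation (default sd 18%), lag-1 autocorrelation 0.2 — and
optional per-decade trends.

*Stands*: even-aged plots initialised with Gaussian DBH; thinning from
below removes the smallest trees until the target basal-area fraction
is gone (overshoot bounded by one tree); background mortality removes
a small constant fraction of stems per year (default 0.5%), smallest
first, in the spirit of self-thinning; inventories are emitted on a
fixed interval.  Cored ("sampled") trees are drawn from above the plot
mean and are excluded from thinning and mortality, mirroring the field
protocol in which sampled trees were above the pre-thinning average
and survived to coring.

*Growth*: each plot-year, covariates are assembled (mean sampled-tree
DBH, plot basal area, the model's climate pools), the plot-mean BAI is
drawn from the Gamma observation model, shared across trees in
proportion to their basal area (so the sampled-tree mean equals the
draw), and inverted to ring widths.  Widths are quantised to 0.01 mm —
the measurement resolution of the emulated instrument — *before* the
realised growth and covariates are recorded.  Consequently writing the
dataset to rwl/CSV and re-ingesting it reproduces the simulator's
internal covariates exactly at inventory years (and to interpolation
accuracy between them), which the test suite asserts at 1e−9.  The
rwl format cannot carry pith offsets, so the generator writes a
sidecar CSV (`pith_offsets.csv`) that the reader joins.

*Five-site fixture*: one xeric-oak, two mesic-oak and two pine
archetypes, each parameterised with its published response-function
values (the pine model shares parameters across its two sites except
the competition intercept, 0.666 vs 1).  The Gamma shape is set to 20
(CV ≈ 22%), a value typical of plot-mean BAI noise; the published
tables do not report a dispersion.  Initial densities, diameters and
per-site thinning fractions were calibrated once so that each site's
simulated basal area stays within the published per-site min–max band
over the 36-year run; the mesic sites use lighter effective removal
fractions than the nominal 15–50% menu because those bands are narrow
and the real sites were established later (hence thinned fewer times)
than the uniform simulated span.

*Recovery experiment* (`simulate_observations`): a lighter generator
used for estimator validation — 40 plots × 40 years with monotone size
trajectories, smoothly varying basal-area paths, and independent
per-plot-year climate draws spanning mean DBH 88–301 mm, basal area
2.4–19 m²/ha, hydrological-year precipitation 280–780 mm and spring
maximum temperature 12–20 °C.  The precipitation span is the
interannual drought-to-wet range around a ~500 mm normal (site *means*
vary much less); that interannual spread is what identifies the
curvature of the saturating precipitation response and hence separates
MG from the modifier plateaus.  Drawing climate independently per
plot-year treats plots as spread along a climatic gradient and
maximises the information content of n = 1600 observations.

What the generator does **not** emulate: recruitment/regeneration,
spatially explicit competition, individual-tree climate-response
heterogeneity, crossdating error, missing rings, multi-stem coppice
architecture, and autocorrelated growth residuals beyond what the
covariates induce.  Passing tests on these data therefore demonstrate
the correctness of the algorithms and the internal consistency of the
pipeline, not the field adequacy of the model.

## Numerical choices and degenerate inputs

Invalid parameter regions inside the optimiser return +∞ rather than
raising, so bounded search can traverse them.  The likelihood is
evaluated vectorised over all observations.  Determinism: every
stochastic component takes an explicit integer seed; generator streams
are derived from one master seed via named CRC-tagged SeedSequences,
so stages can be regenerated independently and runs are byte-stable.
All problem sizes used in the tests and the acceptance script (plot
counts, year spans, replicate counts, annealing budgets) are stated in
the respective code and were chosen as the smallest sizes at which the
statistical checks are stable.

## Known limitations

* MG is identified only through the joint saturation of the size and
  precipitation responses; with covariates confined to narrow ranges
  its maximum-likelihood estimate can deviate by more than 10% from
  truth in individual realisations even when the optimiser finds the
  exact MLE.
* Support intervals condition on the other parameters (no
  re-profiling by default) and so understate uncertainty along
  correlated ridges.
* The annealing schedule is a robust default, not a benchmark-tuned
  optimum; budget-constrained fits (as in the model-selection power
  experiment) are adequate for AIC differences of hundreds of units
  but not for tight parameter work.
* The control-mode competition ramp is a stylised linear-to-asymptote
  path; real self-thinning trajectories curve.
* No mixed-effects structure: plots within a site are treated as
  exchangeable once the site intercept is applied.
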