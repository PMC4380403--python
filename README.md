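# dendrofit

Nonlinear multiplicative growth–climate–competition modelling for
tree-ring data.

`dendrofit` is for forest ecologists and dendroecologists who want to
model annual tree growth (basal area increment, BAI) as a joint,
*nonlinear* function of tree size, stand competition and climate —
rather than as a linear sum of effects — and to project how growth
would change through the 21st century under climate scenarios and
thinning regimes.

## The model

Plot-level BAI is modelled as maximum potential growth scaled by
unit-interval response functions ("modifiers"):

    BAI = MG · f₁(Size) · f₂(Competition) · f₃(Precipitation) · f₄(Temperature) + ε

* **MG** (mm²/yr) is the growth attained when every covariate is at its
  optimum.
* Each **fᵢ(x) ∈ [0, 1]** is drawn from a catalogue of six families:
  logistic (Hill form, `1/(1+(x/a)^b)`), modified Gaussian, negative
  exponential (`a·e^{bx}`), negative potential, log-normal and modified
  Laplace (`e^{-b|x-a|}`).  Typical choices are a saturating logistic
  for size and precipitation, a negative exponential decay for
  competition (plot basal area, m²/ha), and a peaked Laplace kernel
  for temperature with optimum `a`.
* **ε** is Gamma observation error, mean-parameterised: shape *k*
  (the dispersion), scale *μ/k*, so the error is right-skewed and
  heteroscedastic (variance μ²/k), as raw BAI chronologies are.

Parameters are estimated by maximum likelihood with simulated
annealing (seeded, multi-chain, with a simplex polish), uncertainty is
reported as 2-log-likelihood-unit support intervals, and nested
covariate combinations are compared by ΔAIC (a difference ≥ 2 counts
as real support).

The package also provides the full data pipeline around the model:
Tucson/rwl ring-width ingest, BAI conversion and plot chronology
building (≥ 5 trees per year), annual competition series from periodic
inventories with thinning-event bookkeeping, seasonal climate pooling
(hydrological year, spring, May–July, …) with lapse-rate correction
and Kendall tau-b screening, growth projection (dynamic and
constant-diameter) under bias-adjusted monthly climate scenarios, a
30-year low-pass smoothing spline, and a synthetic-stand generator
that produces complete, study-shaped datasets from a known model.

## Worked example

Simulate a xeric oak site (4 plots, 36 years, thinning from below on
12-year rotations), then fit the nested candidate models to the data
re-ingested from the written rwl/CSV files:

```bash
dendrofit simulate --out data --seed 5 --sites BP
dendrofit fit --data-dir data/BP --out fits --seed 2
```

which prints:

```
         model  log_likelihood  n_params         aic  delta_aic   r2_adj      rmse
          size     -813.985679         4 1635.971359 133.039772 0.280444 76.633602
size_prec_temp     -808.928259         8 1633.856518 130.924931 0.329252 72.916583
     size_comp     -744.364647         5 1498.729294  -4.202292 0.686243 50.421481
      complete     -742.465793         9 1502.931587   0.000000 0.685532 49.741690
selected: size_comp
```

Reading the table: adding competition to the size-only model drops the
AIC by ~137 units (ΔAIC 133 → −4.2 relative to the complete model) and
lifts the adjusted R² from 0.28 to 0.69 — competition carries most of
the explainable growth variability at this site, exactly as the
generating model says it should.  The climate-only candidate
(`size_prec_temp`) barely improves on size alone.  At this small
sample the complete model is *not* selected: it sits within 2 AIC
units of `size_comp`, so the parsimony rule picks the model with fewer
parameters.  On larger samples the climate terms earn their keep (see
the acceptance script's model-selection power result).

The fitted model is an ordinary object you can interrogate:

```python
from dendrofit import GrowthModel
m = GrowthModel.from_text(open("fits/fit_complete.txt").read().split("[fit]")[0])
m.predict(150, 10, 600, 16.1)   # size mm, BA m²/ha, P_Hyd mm, Tmax_Spr °C
# -> 238.5  (mean BAI, mm²/yr)
```

Projections run from a fitted (or known) model and a monthly climate
scenario CSV:

```bash
dendrofit project --config proj.yaml --fit-file fits/fit_complete.txt \
    --observed-climate data/BP/climate.csv --out projections
```

writing one CSV per scenario × competition regime (control vs heavy
thinning) × projection mode (dynamic / constant-diameter) × size
class, each with raw and 30-yr-smoothed BAI, the competition path, the
diameter path and an extrapolation flag.

Library users can do all of the above without the CLI: `GrowthML(data,
template).fit()` returns a results object with `params`,
`support_intervals()`, `summary()` and `to_text()`; see the module
docstrings.

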