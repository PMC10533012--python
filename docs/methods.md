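# Methods

`milasso` implements a variable-selection pipeline for datasets that
combine a modest number of observations with many candidate growth
variables, bounded missingness, and known nuisance structure (the
originating lab, encoded as fixed-effect dummies). The motivating
application is the fatty-acid profile of *Nannochloropsis oculata*
compiled across studies, but nothing in the pipeline is specific to it.

## The statistical procedure

**Bounded multiple imputation.** Every missing predictor cell carries a
`[lower, upper]` interval derived from a mechanistic or empirical bound
model (see below). The sampler fills each missing cell with an
independent uniform draw on its interval, m times (default m = 10),
yielding m completed datasets. Uniform is the maximum-entropy choice
when only limits are credible; the draw-distribution tag is stored so
alternatives can be added without a format change. No joint model
across variables is attempted — the bounds are the only information the
imputation uses, and cells are filled independently. Temporal-average
features are recomputed per imputation after the daily series are
filled, so derived columns stay consistent with their sources.

**Round 1 — LASSO screen.** Per imputation and response, predictors are
z-scored,

    x_ij' = (x_ij - mean_j) / sd_j      (sample SD, n-1),

the response is mean-centered so the intercept is never penalized, and
the LASSO objective

    (1/2n) * sum_i (y_i - b0 - sum_j b_j x_ij')^2 + lambda * sum_j |b_j|

is minimized by cyclic coordinate descent over a descending log-spaced
grid of 100 lambdas from lambda_max = max_j |x_j'y|/n down to 1e-3 of
it, with warm starts. 10-fold cross-validation (fold standardization
re-estimated on training folds only) yields the CV curve. Three lambdas
are read off it:

* **MinMSE** — smallest mean CV error (ties go to the larger lambda);
* **1SE** — largest lambda whose CV error is within one standard error
  of the minimum;
* **NoBlocking** — the smallest grid lambda at which every blocking
  (data-origin) dummy has an exactly zero coefficient. The rationale:
  if the origin dummies are excluded while real predictors remain, the
  origin carries no information beyond what the predictors explain.

Per criterion, a variable survives the screen when the 80% trimmed mean
of its absolute standardized coefficients across the m imputations is
positive — a term retained (however strongly) in only one imputation is
trimmed away. The union of the three criteria's survivors is the
round-1 candidate set. Absolute values are used because genuinely
important effects can be negative; a sign-literal trimmed mean would
discard them.

**Round 1 — stepwise with interactions.** Per imputation, the
candidates plus all their pairwise products (raw scale, as the final
models are meant to be interpretable in original units) enter a
stepwise linear regression with F-test add/remove thresholds
penter = 0.05 and premove = 0.10 (the documented defaults of the MATLAB
tool this stage mirrors). The procedure starts from the full candidate
model when it is full rank and leaves at least 10 residual df;
otherwise it falls back to forward selection from the intercept-only
model — a near-saturated start has ~zero residual SSE, every p-value
collapses, and nothing could ever be pruned. Blocking dummies may enter
as main effects but are never crossed into interactions: an
origin-specific slope is not a blocking adjustment, and products of a
dummy with a real predictor would smuggle predictor signal into the
blocking block of round 2. Interactions are not required to keep their
main effects ("no hierarchy"): a pure product signal is representable.
Ties on p-values break lexicographically for cross-platform
determinism. A census counts which terms appear in which imputations.

**Round 2 — LASSO under NoBlocking, final stepwise, pooling.** The
census terms (interactions materialized as raw products, then z-scored)
plus all blocking dummies form the round-2 design; lambda is chosen by
NoBlocking only, where the blocking block includes any term involving a
dummy. Terms surviving the trimmed-|coefficient| rule define the final
pool: the mains appearing individually or inside a surviving
interaction, plus the surviving interactions themselves. A final
per-imputation stepwise fit on that pool is pooled with Rubin's rule:
per term, mean estimate; within-imputation variance W = mean squared
SE; between-imputation variance B = sample variance of estimates;

    T = W + (1 + 1/m) * B,    pooled SD = sqrt(T).

A term absent from an imputation's final model contributes estimate 0,
SE 0 and p-value 1, so the pooled summaries weigh presence across
imputations. p-values are summarized by mean ± SD and the 80% trimmed
mean; the report marks mean p <= 0.05 in bold and trimmed mean <= 0.05
with a dagger. Terms never receive a Barnard–Rubin t-reference — the
reported inference is the per-imputation t-test summary, with the
Rubin SD attached to the estimate only.

## Imputation-bound models

* **Biomass.** Dry weight converts to ash-free dry weight assuming 1%
  (upper) to 20% (lower) ash: bounds (0.80·DW, 0.99·DW). From cell
  counts, the lower series ramps single-cell weight linearly from 10 pg
  to the final per-cell weight; the upper series holds the final
  per-cell weight constant.
* **Nitrate.** Consumption is a quadratic polynomial in biomass change
  and initial nitrate; coefficients are configuration (default: 60 mg N
  consumed per g AFDW formed, a 6% nitrogen quota) with a refit routine
  for when consumption series are available. The lower nitrate bound
  pairs with the upper biomass trajectory and vice versa; both clamp to
  [0, initial].
* **Phosphate.** Biomass phosphorus content between 0.5% (minimal
  quota) and 2.5% (luxury uptake) bounds the residual phosphate.
* **pH / inorganic carbon.** A self-contained carbonate-equilibrium
  solver pins CO2(aq) by Henry's law and finds the unique root of the
  proton condition on pH in [2, 12] by Brent's method. Constant sets:
  Weiss (1974) K0 + Lueker et al. (2000) K1/K2 + Millero Kw for
  seawater, Plummer & Busenberg (1982) for dilute media; chosen by
  salinity (< 5 automatically selects freshwater) or explicitly. A
  linear residual model in (dN, dP, aeration rate) refines the
  equilibrium pH on the proton-activity scale, with a configurable
  activity floor (1e-12) guarding the back-transform. Non-aerated
  cultures take a zero lower bound and the air-equilibrium value as the
  upper bound for inorganic carbon.
* **Illumination.** For cylinders of unknown diameter d in [5, 10] cm
  lit from one side, the illuminated area is approximated by the
  projected area d·h with h = 4V/(pi d²), so photon flux per volume is
  4I/(pi d); the diameter range gives the bounds. No ray tracing.

## The synthetic study

The generator emulates the structure of the real compilation with known
sparse truth. Defaults (the standing study conditions for all recovery
results): n = 121 observations; 40 numeric predictors, the first 6
temporal with AR(1) daily series (rho = 0.8, innovation scale 0.3)
around a per-observation level so 2/3/4-day averages correlate strongly
with the harvest-day value; 4 origin groups encoded as 3 blocking
dummies; 3 nitrogen-source levels as 2 predictor dummies; 5 true main
effects with |beta| in 1.0–2.0 and 2 true pairwise interactions among
those mains; Gaussian noise SD 0.25; 15% missingness, completely at
random, on numeric predictor cells and daily-series values; bounds
centered on the truth with relative half-width 0.3 (floor 0.05).
Concentration-like predictors are standard log-normal, temperature/pH-
like ones uniform on (0, 1).

Two deliberate choices deserve emphasis:

* **True interactions sit among true mains.** A two-round screen that
  selects main effects first can only discover an interaction whose
  factors survive round 1; an interaction between two variables with no
  main effect is structurally invisible to this pipeline (a known
  limitation of screening-then-interacting strategies).
* **Origin offsets default to zero.** The NoBlocking criterion presumes
  that origin differences are carried by the measured growth variables;
  the default design satisfies that premise. When origin carries strong
  signal orthogonal to all predictors, the criterion degenerates toward
  lambda_max and screens out nearly everything — exercised in the test
  suite as the sensitivity case, and visible in practice as the
  "blocking nonzero at every lambda" warning.

What passing the synthetic recovery does **not** show about real data:
missingness in the wild is rarely MCAR; real bound intervals are not
centered on the truth; predictors are cross-correlated in ways the
generator does not emulate; and the per-imputation stepwise stage
retains noise terms whose in-sample p-values are biased by selection,
so significance flags on real data overstate evidence (no
multiple-testing control is applied, matching the reported procedure).

## Numerical choices

* Coordinate descent uses covariance (Gram) updates with an
  incrementally maintained gradient and an active-set strategy (full
  sweeps alternate with sweeps over the nonzero set); convergence is
  max |coefficient change| < 1e-7 with a 1e5 sweep cap. The inner loop
  is compiled with numba when available; a pure-Python reference
  implementation with identical semantics is the fallback.
* KKT residuals certify optimality in tests: for zero coefficients
  |x_j'r/n| <= lambda + tol, else x_j'r/n = lambda·sign(b_j) ± tol.
* Zero-variance columns are dropped (and logged) before z-scoring;
  an all-zero-variance design is an error.
* The stepwise cycle guard records visited models and per-size best
  SSE; a step that revisits either terminates the loop.
* Trimmed means drop floor(((1-retain)/2)·n + 1e-9) values per tail;
  the epsilon keeps e.g. 0.1·10 from flooring to 0 in floating point.
* Report numbers are formatted deterministically (fixed mantissa/
  exponent rule), so byte-identical reports certify end-to-end
  determinism.

## Problem sizes in the checks

The acceptance script exercises: 100 random LASSO instances (n = 30,
p = 5) against a bound-constrained convex oracle; 1e6 imputation cell
draws; a 20-point pCO2 sweep plus 20 random media against a bisection
oracle; 1000 stepwise type-I replicates (n = 40); the default synthetic
study over 10 seeds for recovery; and a reduced study (n = 60, 12
predictors) twice for byte-identical-report determinism.

## Known limitations

* Imputation noise acts as measurement error in the completed designs;
  with 15% missingness this yields a few systematically significant
  noise terms per run (errors-in-variables), which the procedure has no
  mechanism to remove — reflected in the small false-positive count of
  the recovery results.
* The NoBlocking lambda is a single path statistic; it inherits the
  instability of LASSO entry points under strong collinearity.
* The carbonate solver ignores ion pairing, borate/phosphate buffering
  and activity corrections beyond the chosen stoichiometric constants;
  the residual pH model absorbs the resulting bias where calibration
  data exist.
* Stepwise p-values are conditional on the selected model and biased by
  the search; they rank terms rather than test hypotheses.
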