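# Methods

## Model

The package predicts a continuous spatial response `y(x)` observed at `n`
point locations with `p` covariates as trend plus spatially correlated
residual (regression kriging with machine-learning trends):

```
ŷ(x₀) = m̂(x₀) + ê(x₀)
```

**Trend `m̂`.**  Either of two learners, fitted to the covariates only:

- *Boosted regression trees* (BRT): gradient boosting for squared-error loss.
  `F₀ = mean(y)`; each of `nTrees` iterations fits a depth-limited regression
  tree to the current residuals on a random `bag_fraction` subsample and adds
  it scaled by the learning rate.  Implemented on top of scikit-learn's
  `GradientBoostingRegressor`; the package adds the trend contract, nested
  split-record serialization and relative-influence normalization.
- *Lasso*: cyclic coordinate descent with soft-thresholding for

  `min (1/N) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ‖β‖₁`

  with an unpenalised intercept.  The penalty is interpreted on this
  (1/N)-RSS scale everywhere (grids, CLI, serialization); the equivalent
  scikit-learn `Lasso` parameter is `alpha = λ/2`, and the all-zero threshold
  is `λ_max = max_j |(2/N) x_jᵀ(y − ȳ)|`.  For an orthonormal design scaled so
  that `XᵀX = N·I`, the solution is the OLS coefficient soft-thresholded at
  `λ/2` — the analytic oracle the tests check against.

**Residual kriging `ê`.**  Ordinary kriging of the trend's training residuals
`e(xᵢ) = y(xᵢ) − m̂(xᵢ)`: at each target the `nMax` nearest residuals (plain
Euclidean distance, ties broken by ascending row index) enter a bordered
linear system built from the fitted semivariogram with a Lagrange multiplier
enforcing `Σλᵢ = 1` (unbiasedness under an unknown locally constant mean).
The residual mean is *not* assumed zero globally.  The semivariogram is
always the spherical model

```
γ(h) = c0 + c1·(1.5·h/a − 0.5·(h/a)³)   for 0 < h ≤ a,
γ(h) = c0 + c1                           for h > a,     γ(0) = 0,
```

with nugget `c0`, partial sill `c1`, range `a`.  `γ(0) = 0` makes kriging an
exact interpolator at observed locations regardless of the nugget; the nugget
applies to all strictly positive lags.

**Baselines.**  Plain OK kriges the (transformed) response itself with a
variogram fitted to it, ignoring covariates; plain BRT uses the trend alone.

## Estimation choices

- *Empirical variogram*: binned Matheron estimator,
  `γ̂(h_b) = Σ (yᵢ−yⱼ)² / (2·N_b)`; default 15 equal-width bins with cutoff
  one-third of the maximum pairwise distance (the customary gstat-style
  default; both configurable).  Empty bins are dropped; an all-zero variogram
  (constant field) is an error rather than a silent zero fit.
- *Spherical fit*: weighted least squares with weights `N_b / h_b²`, bounds
  `c0, c1 ≥ 0`, `a > 0`, via `scipy.optimize.least_squares` from several
  starting points (lowest cost kept).  When the fitted structured component
  contributes less than 1e-8 of the sill over all observed lags, the fit is
  canonicalised to pure nugget (`c1 = 0`, range pinned at its lower bound):
  the range is unidentifiable there and pinning it keeps results
  deterministic.
- *Kriging numerics*: the bordered system is solved densely per target
  (`nMax ≤ 150` keeps it small).  Exactly duplicated neighbor locations are
  rejected up front with the offending indices (the system would be singular
  at zero nugget); a dataset-level `average_duplicates()` switch collapses
  them.  Computed variances in `[−1e-8, 0)` are clamped to zero; anything
  more negative is an error.
- *Lasso convergence*: tolerance 1e-7 on the maximum absolute coefficient
  change per sweep, at most 1e5 sweeps; non-convergence raises an error
  carrying the last iterate rather than returning it silently.
- *BRT defaults*: learning rate 0.1, depth-1 stumps, bag fraction 0.5, one
  seed governing all bagging draws (recorded in the model).  Only `nTrees`
  is treated as tuned.

## Preprocessing and the evaluation protocol

Covariates are standardized to zero mean / unit variance; a skewed response
can be log-transformed as `log(y + offset)` with a configurable offset
(default 1, covering zero-valued cover data).  All fitting **and** all
reported RMSEs live on the transformed scale; no back-transform bias
correction is attempted.  Standardization is global by default (fitted once
on the full dataset before CV, matching the workflow the method targets); a
strict per-fold mode is available via the preprocessor API for
leakage-sensitive uses.

Accuracy is RMSE over held-out points, pooled across the folds of a k-fold
(default 10) cross-validation.  Within every training fold the entire model
is refitted — including the residual variogram for hybrids and the response
variogram for OK.  Grid search covers `nMax` 10–150 (step 5), `nTrees`
100–800 (step 50) and `λ` 0.01–1 (step 0.005), with ties broken toward the
smaller `nMax`, then the smaller second parameter.  Repeated CV re-partitions
the data `repeats` times with per-repeat seeds derived deterministically from
the master seed; all algorithms share the identical partition within a
repeat, which is what makes the per-repeat RMSE vectors proper pairs for the
two-sided paired-samples t-test.  Optimal parameters are selected once and
then held fixed across repeats (re-running grid search inside every repeat is
supported by composing the API but is not the default).

A guard enforces the minimum training size `n > 2p + 20` for hybrid fits
(98 points at p = 39).  Below it, hybrid trends overfit and their residual
variograms are estimated from too few points; plain OK is the recommended
model in that regime.  The guard raises by default and downgrades to a
warning when explicitly overridden — CV on deliberately small datasets does
exactly that.

## Variable importance

BRT importance is the classical relative influence: each covariate's share of
the total squared-error reduction over all splits of all trees, normalized to
sum to 100 (all-zero with a flag for a constant response).  Lasso importance
is variable selection — the nonzero-coefficient set — ranked by absolute
standardized coefficient; the magnitude ranking is a documented convention on
top of the primary selection signal.  Hybrid models inherit their trend's
importance unchanged: residual kriging attributes nothing to covariates.
Across datasets, the top-k frequency ranking counts the datasets in which
each variable reaches a model's top-k (zero-score variables never qualify),
sorted by decreasing frequency with deterministic name tie-breaks.  Ablation
re-runs cross-validation with named covariates removed on the identical fold
partition, so the RMSE delta is a paired comparison.

## Synthetic study conditions

The generator draws uniform locations on the unit square, i.i.d. standard
normal covariates (optionally sharing a latent factor to emulate
multicollinearity), and builds the response as trend + Gaussian random field
+ white noise.  The field has spherical covariance `C(h) = sill − γ(h)` for
`h > 0` (nugget as spatially white variance) and is drawn by dense Cholesky
factorisation with a 1e-10 jitter retry, capping `n` at 3000 — desk scale by
design; field-scale inventories (tens of thousands of plots) are outside the
fixture scope.  Two trend families: `linear-sparse` (a few linear effects)
and `nonlinear-interaction` (linear + centered quadratic + saturating main
effects plus one pairwise interaction, so tree ensembles have a genuine
advantage over a linear trend).

The default benchmark is `n = 800`, `p = 10`, three active covariates with
effects (1.0, 0.7, 0.5), nonlinear trend, residual field `c0 = 0.1`,
`c1 = 0.5`, `a = 0.3`, noise sd 0.2.  The range 0.3 is an order of magnitude
above the typical nearest-neighbor spacing (~0.035 at n = 800), i.e. the
regime with real spatial information in the residuals; the structured
residual sd (~0.7) dominates the nugget + noise floor, so residual kriging
has something to recover, without being so strong that the trend is
irrelevant.  These values were fixed once as the package's study conditions.
What passing tests on these conditions show is that the method's machinery is
correct and that its qualitative behaviour (hybrid advantage, small-n
failure, importance recovery) emerges when its assumptions hold; they say
nothing about any particular field dataset, where trends are weaker,
sampling is irregular and covariates are far from Gaussian.

Problem sizes used by the test suite and acceptance script: benchmark
repeated CV at 100 repeats (test suite) and 30 repeats (acceptance script) of
10-fold CV on n = 800; variogram recovery over 20 fields of n = 400;
small-sample regime at n = 90, p = 39 with 10–20 repeats; importance recovery
over 20 seeds of n = 300.  These sizes make the full suite run in minutes on
a single CPU while leaving every comparison grossly significant.

## Known limitations

- Isotropic spherical variograms only; no anisotropy, no exponential or
  Gaussian families, no universal/co-kriging.
- Distances are planar Euclidean; latitude/longitude are treated as planar
  degrees (mirroring common practice on regional extents), and no great-circle
  option is enabled by default.
- The kriging neighborhood is purely count-based (`nMax`); no radius cap or
  minimum-neighbor rule.
- Trend uncertainty is ignored: reported variances cover the residual-kriging
  component only.
- No back-transform bias correction for log-transformed responses.
- Whether BRTOK or LASOK wins is data-dependent; the package deliberately
  leaves the choice to the user rather than imposing a tie-break rule.
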