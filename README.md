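# resok — hybrid machine-learning / geostatistical spatial prediction

`resok` predicts a continuous point-referenced response (the motivating case
is log invasive-plant cover on forest-inventory plots, described by dozens of
ecological covariates) by combining a machine-learning mean surface with
ordinary kriging of its residuals:

```
ŷ(x₀) = m̂(x₀) + ê(x₀),        ê(x₀) = Σᵢ λᵢ e(xᵢ)
```

where `m̂` is a trend model fitted to the covariates — boosted regression
trees (**BRTOK**) or the lasso (**LASOK**) — `e(xᵢ) = y(xᵢ) − m̂(xᵢ)` are its
training residuals, and the kriging weights `λᵢ` (constrained to sum to one)
are derived from a spherical semivariogram fitted to those residuals, using
only the `nMax` nearest observations per prediction.  The trend captures
nonlinear, high-dimensional covariate effects that plain ordinary kriging
(OK) cannot; the residual kriging recovers the spatially structured variation
the trend leaves behind.  The package is aimed at spatial ecologists and
geostatisticians who want this hybrid alongside its natural baselines.

It provides:

- `geostat` — Matheron empirical variograms, weighted-least-squares spherical
  fitting, local-neighborhood OK with prediction variance;
- `trend` — boosted regression trees and a coordinate-descent lasso behind a
  common trend-model contract;
- `hybrid` — preprocessing (covariate standardization, optional
  log-response), the `n > 2p + 20` sample-size guard, and the three-step
  hybrid construction;
- `evaluation` — k-fold CV with RMSE, grid search over `nMax` / `nTrees` /
  `lambda`, repeated CV with shared fold partitions, paired-samples t-tests;
- `importance` — BRT relative influence (summing to 100), lasso variable
  selection, cross-dataset top-k frequency ranking, ablation re-runs;
- `synthetic` — a generator of datasets with known trend and spherical
  residual-field truth, so every claim is testable without external data;
- a `resok` CLI with `simulate`, `fit`, `evaluate` and `importance`
  subcommands.

## Worked example

```python
import numpy as np
from resok import SimSpec, make_dataset, fit_hybrid, predict_hybrid, importance_table
from resok.evaluation import repeated_cv, rmse_matrix, paired_ttest

data, truth = make_dataset(SimSpec(n=600, seed=42))
train, test = data.subset(np.arange(500)), data.subset(np.arange(500, 600))

model = fit_hybrid(train, "brt", n_max=30)
vm = model.residual_variogram
print(f"residual variogram: nugget={vm.nugget:.3f} partial_sill={vm.partial_sill:.3f} range={vm.range_a:.3f}")

pred = predict_hybrid(model, test.covariates, test.coords)
print(f"hold-out RMSE (BRTOK): {np.sqrt(np.mean((test.target - pred)**2)):.3f}")
print(f"top-3 variables: {importance_table(model).top(3)}  (planted: {truth['active_names']})")

tidy = repeated_cv(train, {"ok": {"n_max": 30}, "brtok": {"n_max": 30, "n_trees": 200}},
                   repeats=5, k=10, seed=0)
mat = rmse_matrix(tidy)
print(f"mean CV-RMSE: ok={mat['ok'].mean():.3f} brtok={mat['brtok'].mean():.3f}")
res = paired_ttest(mat["ok"], mat["brtok"])
print(f"paired t-test: t={res.statistic:.2f}, p={res.pvalue:.2e}")
```

prints

```
residual variogram: nugget=0.394 partial_sill=0.323 range=0.270
hold-out RMSE (BRTOK): 0.838
top-3 variables: ['v2', 'v1', 'v3']  (planted: ['v1', 'v2', 'v3'])
mean CV-RMSE: ok=1.749 brtok=0.775
paired t-test: t=177.36, p=6.06e-09
```

The fitted residual variogram recovers spatial structure the boosted trees
left behind (partial sill 0.32 with range 0.27 on the unit square); the
hybrid's hold-out RMSE of 0.84 sits far below plain OK's 1.75 because OK
ignores the covariate-driven trend entirely, and the paired t-test over five
shared-partition CV repeats confirms the gap is systematic, not partition
luck.  The three planted signal covariates are ranked on top.

The same workflow from the shell:

```sh
resok simulate --n 600 --seed 42 --out runs/sim
resok evaluate --input runs/sim/dataset.csv --algorithms ok,brt,brtok,lasok \
      --k 10 --repeats 5 --out runs/eval
resok importance --input runs/sim/dataset.csv --algorithm brtok --out runs/imp
```

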