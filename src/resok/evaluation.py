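"""Model comparison protocol: k-fold CV, grid search, repeats, paired t-tests.

Four algorithms are compared on identical folds:

- ``ok``     ordinary kriging of the (transformed) response itself,
- ``brt``    boosted-tree trend alone,
- ``brtok``  boosted-tree trend + kriged residuals,
- ``lasok``  lasso trend + kriged residuals.

Accuracy is the root mean squared error over held-out points, pooled across
folds.  Parameter selection is a grid search over each algorithm's tuned
parameters (``nMax`` for the kriging window, ``nTrees`` for the boosted trees,
``lambda`` for the lasso), and the repeated-CV runner re-partitions the data
``repeats`` times, every algorithm sharing the identical partition within a
repeat so per-repeat RMSEs form proper pairs for the paired-samples t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SpatialDataset
from .errors import DataValidationError, ResokError
from .geostat import empirical_variogram, fit_spherical, krige_grid
from .hybrid import fit_hybrid, predict_hybrid
from .trend import BRTConfig, LassoConfig, fit_brt, predict_trend

__all__ = [
    "ALGORITHMS",
    "CVReport",
    "GridSpec",
    "PairedTTestResult",
    "rmse",
    "kfold_split",
    "cross_validate",
    "grid_search",
    "repeated_cv",
    "paired_ttest",
]

ALGORITHMS = ("ok", "brt", "brtok", "lasok")


def rmse(observed, predicted) -> float:
    """Root mean squared error: sqrt(mean((y_i - yhat_i)^2))."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape or observed.size == 0:
        raise DataValidationError(
            f"length mismatch or empty input: {observed.shape} vs {predicted.shape}"
        )
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(predicted))):
        raise DataValidationError("rmse inputs must be finite")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random disjoint exhaustive partition into k folds of near-equal size.

    Fold sizes differ by at most one; the same seed reproduces the partition.
    """
    if not 2 <= k <= n:
        raise DataValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome for one algorithm at one parameter setting."""

    algorithm: str
    params: dict
    fold_rmses: np.ndarray
    pooled_rmse: float
    k: int
    seed: int
    repeat: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fold_rmses", np.asarray(self.fold_rmses, dtype=float))
        if self.pooled_rmse < 0:
            raise DataValidationError("pooled RMSE must be >= 0")


@dataclass(frozen=True)
class GridSpec:
    """Search grids for the tuned parameters.

    Defaults follow the method's stated search windows — nMax 10..150,
    nTrees 100..800, lambda 0.01..1 — at steps 5, 50 and 0.005 respectively.
    """

    n_max_grid: tuple = tuple(range(10, 151, 5))
    n_trees_grid: tuple = tuple(range(100, 801, 50))
    lambda_grid: tuple = field(
        default_factory=lambda: tuple(np.round(np.arange(0.01, 1.0000001, 0.005), 10))
    )

    def __post_init__(self):
        for name in ("n_max_grid", "n_trees_grid", "lambda_grid"):
            grid = tuple(getattr(self, name))
            if len(grid) == 0 or list(grid) != sorted(grid):
                raise DataValidationError(f"{name} must be nonempty and ascending")
            object.__setattr__(self, name, grid)


# ------------------------------------------------------------- fold fitting


def _ok_fit_predict(train, test_coords, params):
    ev = empirical_variogram(
        train, n_bins=params.get("n_bins", 15), cutoff=params.get("cutoff")
    )
    vm = fit_spherical(ev)
    return krige_grid(train, vm, test_coords, params.get("n_max", 30))


def _brt_cfg(params):
    return BRTConfig(
        n_trees=params.get("n_trees", 100),
        learning_rate=params.get("learning_rate", 0.1),
        max_depth=params.get("max_depth", 1),
        bag_fraction=params.get("bag_fraction", 0.5),
        seed=params.get("brt_seed", 0),
    )


def _lasso_cfg(params):
    return LassoConfig(
        penalty=params.get("lambda", 0.01),
        tol=params.get("tol", 1e-7),
        max_iter=params.get("max_iter", 100_000),
    )


def fit_predict_fold(train: SpatialDataset, test: SpatialDataset, algorithm: str, params: dict,
                     allow_small_n: bool = False):
    """Fit one algorithm on a training fold and predict the held-out points."""
    if algorithm == "ok":
        return _ok_fit_predict(train, test.coords, params)
    if algorithm == "brt":
        model = fit_brt(train, _brt_cfg(params))
        return predict_trend(model, test.covariates)
    if algorithm in ("brtok", "lasok"):
        trend_kind = "brt" if algorithm == "brtok" else "lasso"
        cfg = _brt_cfg(params) if algorithm == "brtok" else _lasso_cfg(params)
        model = fit_hybrid(
            train,
            trend_kind,
            trend_cfg=cfg,
            n_max=params.get("n_max", 30),
            variogram_cfg={
                "n_bins": params.get("n_bins", 15),
                "cutoff": params.get("cutoff"),
            },
            allow_small_n=allow_small_n,
        )
        return predict_hybrid(model, test.covariates, test.coords)
    raise DataValidationError(
        f"unknown algorithm {algorithm!r}; choose one of {ALGORITHMS}"
    )


def cross_validate(
    data: SpatialDataset,
    algorithm: str,
    params: dict | None = None,
    k: int = 10,
    seed: int = 0,
    folds: list | None = None,
    allow_small_n: bool = False,
    repeat: int = 0,
) -> CVReport:
    """k-fold cross-validation of one algorithm.

    Each fold is held out in turn; the model (including, for hybrids, the
    per-fold residual variogram, and for plain OK the per-fold response
    variogram) is refitted on the remaining folds.  The pooled RMSE applies
    the error formula to the concatenation of all held-out predictions.
    ``folds`` may be supplied to share a partition across algorithms.
    """
    params = dict(params or {})
    if folds is None:
        folds = kfold_split(data.n, k, seed)
    all_idx = np.arange(data.n)
    predictions = np.full(data.n, np.nan)
    fold_rmses = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        try:
            preds = fit_predict_fold(
                data.subset(train_idx),
                data.subset(test_idx),
                algorithm,
                params,
                allow_small_n=allow_small_n,
            )
        except ResokError as exc:
            raise type(exc)(f"fold {fi} ({algorithm}): {exc}") from exc
        predictions[test_idx] = preds
        fold_rmses.append(rmse(data.target[test_idx], preds))
    return CVReport(
        algorithm=algorithm,
        params=params,
        fold_rmses=np.asarray(fold_rmses),
        pooled_rmse=rmse(data.target, predictions),
        k=len(folds),
        seed=seed,
        repeat=repeat,
    )


# -------------------------------------------------------------- grid search


def _param_points(algorithm: str, grid: GridSpec):
    if algorithm == "ok":
        return [{"n_max": v} for v in grid.n_max_grid]
    if algorithm == "brt":
        return [{"n_trees": v} for v in grid.n_trees_grid]
    if algorithm == "brtok":
        return [
            {"n_max": nm, "n_trees": nt}
            for nm, nt in itertools.product(grid.n_max_grid, grid.n_trees_grid)
        ]
    if algorithm == "lasok":
        return [
            {"n_max": nm, "lambda": lam}
            for nm, lam in itertools.product(grid.n_max_grid, grid.lambda_grid)
        ]
    raise DataValidationError(f"unknown algorithm {algorithm!r}")


def grid_search(
    data: SpatialDataset,
    algorithm: str,
    grid: GridSpec | None = None,
    k: int = 10,
    seed: int = 0,
    base_params: dict | None = None,
    allow_small_n: bool = False,
):
    """Exhaustive CV search over the algorithm's tuned parameters.

    All candidates share the same fold partition.  Returns the minimizer of
    pooled RMSE (ties broken by smaller ``n_max``, then smaller second
    parameter — guaranteed by evaluating candidates in ascending order and
    keeping strict improvements) plus a tidy table of every candidate.
    """
    grid = grid or GridSpec()
    folds = kfold_split(data.n, k, seed)
    rows = []
    best_params, best_rmse = None, np.inf
    for point in _param_points(algorithm, grid):
        params = {**(base_params or {}), **point}
        try:
            report = cross_validate(
                data, algorithm, params, k=k, seed=seed, folds=folds,
                allow_small_n=allow_small_n,
            )
        except ResokError as exc:
            raise type(exc)(f"grid point {point}: {exc}") from exc
        rows.append({"algorithm": algorithm, **point, "rmse": report.pooled_rmse})
        if report.pooled_rmse < best_rmse:
            best_rmse = report.pooled_rmse
            best_params = point
    return best_params, pd.DataFrame(rows)


# -------------------------------------------------------------- repeated CV


def derive_fold_seed(seed: int, repeat: int) -> int:
    """Deterministic sub-seed for repeat ``repeat`` of a run seeded by ``seed``."""
    return int(np.random.SeedSequence([seed, repeat]).generate_state(1)[0] % (2**31))


def repeated_cv(
    data: SpatialDataset,
    algo_params: dict[str, dict],
    repeats: int = 100,
    k: int = 10,
    seed: int = 0,
    allow_small_n: bool = False,
):
    """Repeat k-fold CV with fresh random partitions, algorithms sharing folds.

    ``algo_params`` maps algorithm name to its (already selected) parameter
    setting.  Returns a tidy DataFrame with one row per (repeat, algorithm)
    carrying the pooled and mean-fold RMSE; within a repeat every algorithm
    sees the identical partition, so per-repeat RMSE columns are paired.
    """
    rows = []
    for r in range(repeats):
        fold_seed = derive_fold_seed(seed, r)
        folds = kfold_split(data.n, k, fold_seed)
        for algo, params in algo_params.items():
            report = cross_validate(
                data, algo, params, k=k, seed=fold_seed, folds=folds,
                allow_small_n=allow_small_n, repeat=r,
            )
            rows.append(
                {
                    "repeat": r,
                    "algorithm": algo,
                    "rmse": report.pooled_rmse,
                    "mean_fold_rmse": float(report.fold_rmses.mean()),
                    "fold_seed": fold_seed,
                }
            )
    return pd.DataFrame(rows)


def rmse_matrix(repeated: pd.DataFrame) -> pd.DataFrame:
    """Pivot a repeated_cv table to repeats x algorithms of pooled RMSE."""
    return repeated.pivot(index="repeat", columns="algorithm", values="rmse")


# -------------------------------------------------------------------- tests


@dataclass(frozen=True)
class PairedTTestResult:
    statistic: float
    pvalue: float
    mean_diff: float
    degenerate: bool = False


def paired_ttest(rmse_a, rmse_b) -> PairedTTestResult:
    """Classical paired-samples t-test on per-repeat RMSE differences.

    Two-sided, R - 1 degrees of freedom.  Degenerate cases: identical vectors
    give (t=0, p=1); zero-variance differences with nonzero mean give p=0 with
    the ``degenerate`` flag set.
    """
    a = np.asarray(rmse_a, dtype=float).ravel()
    b = np.asarray(rmse_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise DataValidationError("need two equal-length vectors with R >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTTestResult(0.0, 1.0, 0.0)
        return PairedTTestResult(
            float(np.inf) if mean > 0 else float(-np.inf), 0.0, mean, degenerate=True
        )
    t = mean / (sd / np.sqrt(d.size))
    p = 2.0 * float(stats.t.sf(abs(t), df=d.size - 1))
    return PairedTTestResult(float(t), p, mean)
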