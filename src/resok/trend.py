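"""Mean-surface (trend) learners: boosted regression trees and the lasso.

Both learners implement the same small contract — ``kind``, ``feature_names``,
``predict(X)`` and ``to_dict()`` — so the hybrid combiner can treat them
interchangeably as the trend component ``m_hat`` of a trend + kriged-residual
prediction.

The BRT is a gradient-boosted ensemble for squared-error loss: starting from
the constant mean, each iteration fits a depth-limited regression tree to the
current residuals on a random ``bag_fraction`` subsample and adds it scaled by
the learning rate.

The lasso solves, by cyclic coordinate descent with soft-thresholding,

    min_{b0, b}  (1/N) sum_i (y_i - b0 - x_i' b)^2 + lambda * ||b||_1

with an unpenalised intercept.  The penalty ``lambda`` is interpreted on this
(1/N)-RSS scale throughout the package; the equivalent scikit-learn
``Lasso(alpha)`` parameter is ``alpha = lambda / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from .data import SpatialDataset
from .errors import ConvergenceError, DataValidationError

__all__ = [
    "BRTConfig",
    "LassoConfig",
    "BRTModel",
    "LassoModel",
    "fit_brt",
    "fit_lasso",
    "predict_trend",
    "lasso_lambda_max",
    "trend_from_dict",
]


# ------------------------------------------------------------------ configs


@dataclass(frozen=True)
class BRTConfig:
    """Boosted-tree hyperparameters.

    ``n_trees`` is the tuned parameter (searched 100-800 in evaluation); the
    remaining knobs default to the customary gbm-style settings: learning rate
    0.1, additive stumps (depth 1), bagging fraction 0.5.
    """

    n_trees: int = 100
    learning_rate: float = 0.1
    max_depth: int = 1
    bag_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise DataValidationError("n_trees must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise DataValidationError("learning_rate must be in (0, 1]")
        if self.max_depth < 1:
            raise DataValidationError("max_depth must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise DataValidationError("bag_fraction must be in (0, 1]")


@dataclass(frozen=True)
class LassoConfig:
    penalty: float = 0.01
    tol: float = 1e-7
    max_iter: int = 100_000

    def __post_init__(self):
        if self.penalty < 0:
            raise DataValidationError("penalty must be >= 0")


# ------------------------------------------------------------------- models


def _check_X(X, p, label="X"):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataValidationError(f"{label} must be 2-dimensional")
    if X.shape[1] != p:
        raise DataValidationError(
            f"{label} has {X.shape[1]} columns but the model was fitted with p={p}"
        )
    return X


def _tree_to_records(tree, node=0):
    """Recursive nested-split record of one fitted sklearn regression tree."""
    if tree.children_left[node] == -1:
        return {"leaf": float(tree.value[node, 0, 0])}
    return {
        "feature": int(tree.feature[node]),
        "threshold": float(tree.threshold[node]),
        "left": _tree_to_records(tree, tree.children_left[node]),
        "right": _tree_to_records(tree, tree.children_right[node]),
    }


def _eval_tree_records(rec, X):
    if "leaf" in rec:
        return np.full(X.shape[0], rec["leaf"])
    go_left = X[:, rec["feature"]] <= rec["threshold"]
    out = np.empty(X.shape[0])
    out[go_left] = _eval_tree_records(rec["left"], X[go_left])
    out[~go_left] = _eval_tree_records(rec["right"], X[~go_left])
    return out


class BRTModel:
    """Fitted boosted-regression-tree trend.

    Backed either by a live scikit-learn ensemble (after :func:`fit_brt`) or by
    serialized nested-split records (after :meth:`from_dict`); both evaluate to
    the same additive prediction ``F0 + lr * sum_t tree_t(x)``.
    """

    kind = "brt"

    def __init__(self, *, feature_names, config, estimator=None, records=None,
                 baseline=None, importance=None, train_deviance=None):
        self.feature_names = tuple(feature_names)
        self.config = config
        self._estimator = estimator
        self._records = records
        self._baseline = baseline
        self._importance = importance
        self._train_deviance = train_deviance

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def train_deviance(self) -> np.ndarray:
        """In-bag squared-error deviance after each boosting iteration."""
        if self._train_deviance is None:
            raise DataValidationError("training deviance unavailable on a loaded model")
        return np.asarray(self._train_deviance)

    @property
    def importance_scores(self) -> np.ndarray:
        """Per-feature split-gain shares, normalized to sum to 100 (or all zero)."""
        if self._importance is not None:
            return np.asarray(self._importance, dtype=float)
        return self._estimator.feature_importances_ * 100.0

    def predict(self, X):
        X = _check_X(X, self.n_features)
        if self._estimator is not None:
            return self._estimator.predict(X)
        out = np.full(X.shape[0], self._baseline)
        for rec in self._records:
            out += self.config.learning_rate * _eval_tree_records(rec, X)
        return out

    def staged_components(self, X):
        """Baseline and each scaled tree's contribution — the explicit additive sum."""
        X = _check_X(X, self.n_features)
        if self._estimator is not None:
            trees = [est[0].tree_ for est in self._estimator.estimators_]
            records = [_tree_to_records(t) for t in trees]
            baseline = float(self._estimator.init_.constant_[0, 0])
        else:
            records, baseline = self._records, self._baseline
        parts = [np.full(X.shape[0], baseline)]
        for rec in records:
            parts.append(self.config.learning_rate * _eval_tree_records(rec, X))
        return parts

    def to_dict(self) -> dict:
        if self._estimator is not None:
            records = [
                _tree_to_records(est[0].tree_) for est in self._estimator.estimators_
            ]
            baseline = float(self._estimator.init_.constant_[0, 0])
        else:
            records, baseline = self._records, self._baseline
        return {
            "format_version": 1,
            "kind": "brt",
            "feature_names": list(self.feature_names),
            "config": {
                "n_trees": self.config.n_trees,
                "learning_rate": self.config.learning_rate,
                "max_depth": self.config.max_depth,
                "bag_fraction": self.config.bag_fraction,
                "seed": self.config.seed,
            },
            "baseline": baseline,
            "trees": records,
            "importance": [float(v) for v in self.importance_scores],
        }

    @classmethod
    def from_dict(cls, d) -> "BRTModel":
        cfg = BRTConfig(**d["config"])
        return cls(
            feature_names=d["feature_names"],
            config=cfg,
            records=d["trees"],
            baseline=float(d["baseline"]),
            importance=d.get("importance"),
        )


@dataclass(frozen=True)
class LassoModel:
    """Fitted lasso trend: unpenalised intercept plus sparse slope vector."""

    intercept: float
    coef: np.ndarray
    penalty: float
    feature_names: tuple[str, ...]
    n_iter: int = 0
    kind: str = field(default="lasso")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def selected(self) -> np.ndarray:
        """Indices of covariates kept in the model (nonzero coefficients)."""
        return np.flatnonzero(self.coef != 0.0)

    def predict(self, X):
        X = _check_X(X, self.n_features)
        return self.intercept + X @ self.coef

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "kind": "lasso",
            "feature_names": list(self.feature_names),
            "penalty": self.penalty,
            "intercept": self.intercept,
            "coef": [float(c) for c in self.coef],
        }

    @classmethod
    def from_dict(cls, d) -> "LassoModel":
        return cls(
            intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], dtype=float),
            penalty=float(d["penalty"]),
            feature_names=tuple(d["feature_names"]),
        )


def trend_from_dict(d):
    """Rehydrate a serialized trend model of either kind."""
    if d.get("kind") == "brt":
        return BRTModel.from_dict(d)
    if d.get("kind") == "lasso":
        return LassoModel.from_dict(d)
    raise DataValidationError(f"unknown trend kind {d.get('kind')!r}")


# ------------------------------------------------------------------ fitting


def fit_brt(data: SpatialDataset, cfg: BRTConfig | None = None) -> BRTModel:
    """Fit the boosted-tree trend on the dataset's covariates.

    Gradient boosting for squared error: F0 = mean(y); each of ``n_trees``
    iterations fits a depth-``max_depth`` tree to the residuals on a
    ``bag_fraction`` subsample and adds it scaled by ``learning_rate``.
    A constant response yields a model predicting that constant.
    """
    cfg = cfg or BRTConfig()
    if data.p < 1:
        raise DataValidationError("BRT needs at least one covariate (p >= 1)")
    if data.n < 2:
        raise DataValidationError("BRT needs at least two observations")
    est = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=cfg.n_trees,
        learning_rate=cfg.learning_rate,
        max_depth=cfg.max_depth,
        subsample=cfg.bag_fraction,
        random_state=cfg.seed,
    )
    est.fit(data.covariates, data.target)
    return BRTModel(
        feature_names=data.covariate_names,
        config=cfg,
        estimator=est,
        train_deviance=est.train_score_.copy(),
    )


def soft_threshold(z, t):
    """sign(z) * max(|z| - t, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def lasso_lambda_max(X, y) -> float:
    """Smallest penalty shrinking every slope to zero: max_j |(2/N) x_j'(y - ybar)|."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    return float(np.max(np.abs(2.0 / n * X.T @ (y - y.mean())))) if X.shape[1] else 0.0


def fit_lasso(
    data: SpatialDataset,
    penalty: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> LassoModel:
    """Cyclic coordinate descent for the (1/N)-scaled lasso objective.

    Coefficients are updated one at a time by exact univariate soft-threshold
    minimisation; the intercept stays unpenalised.  Convergence is declared
    when the largest absolute coefficient change over a full sweep drops below
    ``tol``.  Covariates are expected to be standardized (see the hybrid
    module's preprocessor); the update is nevertheless exact for any scaling.
    """
    if data.n < 2:
        raise DataValidationError("lasso needs at least two observations")
    if penalty < 0:
        raise DataValidationError("penalty must be >= 0")
    X = data.covariates
    y = data.target
    n, p = X.shape
    zj = 2.0 / n * np.einsum("ij,ij->j", X, X)  # curvature of each coordinate
    beta = np.zeros(p)
    b0 = float(y.mean())
    resid = y - b0  # y - b0 - X @ beta, maintained incrementally
    n_iter = 0
    max_delta = np.inf
    for n_iter in range(1, max_iter + 1):
        max_delta = 0.0
        shift = float(resid.mean())
        if shift != 0.0:
            b0 += shift
            resid -= shift
            max_delta = abs(shift)
        for j in range(p):
            if zj[j] == 0.0:
                continue
            rho = 2.0 / n * (X[:, j] @ resid) + zj[j] * beta[j]
            bj = soft_threshold(rho, penalty) / zj[j]
            if bj != beta[j]:
                resid -= X[:, j] * (bj - beta[j])
                max_delta = max(max_delta, abs(bj - beta[j]))
                beta[j] = bj
        if max_delta < tol:
            break
    else:
        raise ConvergenceError(
            f"lasso coordinate descent did not converge in {max_iter} sweeps "
            f"(last max coefficient change {max_delta:.3e})",
            last_iterate=(b0, beta.copy()),
            last_change=max_delta,
        )
    return LassoModel(
        intercept=b0,
        coef=beta,
        penalty=float(penalty),
        feature_names=data.covariate_names,
        n_iter=n_iter,
    )


def predict_trend(model, X):
    """Evaluate a fitted trend model on an ``m x p`` covariate matrix."""
    return model.predict(X)
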