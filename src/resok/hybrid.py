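"""Trend + kriged-residual hybrid models (regression kriging).

The hybrid prediction at a new location ``x0`` is

    y_hat(x0) = m_hat(x0) + e_hat(x0)

where ``m_hat`` is a fitted machine-learning trend (boosted trees or lasso on
the covariates) and ``e_hat`` is the ordinary-kriging interpolation of the
trend's training residuals ``e(x_i) = y(x_i) - m_hat(x_i)``, using a spherical
variogram fitted to those residuals and an ``nMax``-nearest-neighbor window.
Construction is the three-step recipe: fit the trend, derive residuals at all
training locations, krige the residuals at new locations and add.

Preprocessing follows the study design the method targets: covariates
standardized to zero mean / unit variance, and an optional log(y + offset)
transform of a skewed response such as percent invasive cover.  Model fitting
and evaluation then happen on the transformed scale.

A sample-size guard enforces ``n > 2p + 20``: with fewer training points than
twice the covariate dimension plus twenty, hybrid models are unreliable and
plain ordinary kriging is the recommended fallback.  The guard can be
overridden, in which case it downgrades to a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SpatialDataset
from .errors import DataValidationError, SampleSizeError, SmallSampleWarning
from .geostat import (
    VariogramModel,
    empirical_variogram,
    fit_spherical,
    krige_grid,
)
from .trend import (
    BRTConfig,
    LassoConfig,
    fit_brt,
    fit_lasso,
    predict_trend,
    trend_from_dict,
)

__all__ = [
    "Preprocessor",
    "HybridModel",
    "preprocess_fit",
    "fit_hybrid",
    "predict_hybrid",
    "min_training_size",
    "check_sample_size",
]


def min_training_size(p: int) -> int:
    """Minimum training size for a p-covariate hybrid model: 2p + 20."""
    return 2 * p + 20


def check_sample_size(n: int, p: int, override: bool = False) -> None:
    """Enforce n > 2p + 20; warn instead of raising when ``override`` is set."""
    floor = min_training_size(p)
    if n > floor:
        return
    msg = (
        f"training size n={n} does not exceed the minimum 2p + 20 = {floor} "
        f"for p={p} covariates; hybrid models are unreliable here and plain "
        "ordinary kriging is recommended"
    )
    if override:
        warnings.warn(msg, SmallSampleWarning, stacklevel=3)
    else:
        raise SampleSizeError(msg + " (pass allow_small_n=True to override)")


# -------------------------------------------------------------- preprocess


@dataclass(frozen=True)
class Preprocessor:
    """Covariate standardizer plus optional log-response transform.

    Stores per-feature means and standard deviations from the fitting data so
    the identical affine map applies to new points.
    """

    means: np.ndarray
    sds: np.ndarray
    feature_names: tuple[str, ...]
    log_response: bool = False
    log_offset: float = 1.0

    @classmethod
    def fit(cls, data: SpatialDataset, log_response=False, log_offset=1.0) -> "Preprocessor":
        means = data.covariates.mean(axis=0) if data.p else np.empty(0)
        sds = data.covariates.std(axis=0, ddof=0) if data.p else np.empty(0)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            bad = [data.covariate_names[j] for j in zero]
            raise DataValidationError(f"zero-variance covariates: {bad}")
        return cls(
            means=means,
            sds=sds,
            feature_names=data.covariate_names,
            log_response=bool(log_response),
            log_offset=float(log_offset),
        )

    def transform_covariates(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.means) / self.sds

    def inverse_transform_covariates(self, Z):
        return np.asarray(Z, dtype=float) * self.sds + self.means

    def transform_response(self, y):
        y = np.asarray(y, dtype=float)
        if not self.log_response:
            return y.copy()
        shifted = y + self.log_offset
        if np.any(shifted <= 0):
            raise DataValidationError(
                f"log transform needs y + offset > 0 (offset={self.log_offset})"
            )
        return np.log(shifted)

    def inverse_transform_response(self, z):
        z = np.asarray(z, dtype=float)
        if not self.log_response:
            return z.copy()
        return np.exp(z) - self.log_offset

    def apply(self, data: SpatialDataset) -> SpatialDataset:
        if data.covariate_names != self.feature_names:
            raise DataValidationError("covariate names differ from the fitted schema")
        return replace(
            data,
            covariates=self.transform_covariates(data.covariates),
            target=self.transform_response(data.target),
        )


def preprocess_fit(
    data: SpatialDataset, log_response: bool = False, log_offset: float = 1.0
):
    """Fit the preprocessor on ``data`` and return it with the transformed data."""
    prep = Preprocessor.fit(data, log_response=log_response, log_offset=log_offset)
    return prep, prep.apply(data)


# ------------------------------------------------------------------ hybrid


@dataclass(frozen=True)
class HybridModel:
    """Fitted trend + residual-kriging bundle.

    ``train_residuals`` are observed minus trend-fitted values at the training
    locations; their mean is not assumed zero (ordinary kriging only assumes a
    locally constant mean of the residual field).
    """

    trend: object
    residual_variogram: VariogramModel
    train_coords: np.ndarray
    train_residuals: np.ndarray
    n_max: int

    def __post_init__(self):
        if self.train_coords.shape[0] != self.train_residuals.shape[0]:
            raise DataValidationError("residuals length must match training coords")
        if self.n_max < 1:
            raise DataValidationError("n_max must be >= 1")

    @property
    def trend_kind(self) -> str:
        return self.trend.kind

    def save(self, directory) -> None:
        """Write trend JSON, variogram JSON and residual-table CSV to a directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "trend.json").write_text(json.dumps(self.trend.to_dict(), indent=2))
        meta = {"n_max": self.n_max, "variogram": self.residual_variogram.to_dict()}
        (d / "variogram.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(
            {
                "x": self.train_coords[:, 0],
                "y": self.train_coords[:, 1],
                "residual": self.train_residuals,
            }
        ).to_csv(d / "residuals.csv", index=False)

    @classmethod
    def load(cls, directory) -> "HybridModel":
        d = Path(directory)
        trend = trend_from_dict(json.loads((d / "trend.json").read_text()))
        meta = json.loads((d / "variogram.json").read_text())
        res = pd.read_csv(d / "residuals.csv")
        return cls(
            trend=trend,
            residual_variogram=VariogramModel.from_dict(meta["variogram"]),
            train_coords=res[["x", "y"]].to_numpy(dtype=float),
            train_residuals=res["residual"].to_numpy(dtype=float),
            n_max=int(meta["n_max"]),
        )


def fit_hybrid(
    data: SpatialDataset,
    trend_kind: str,
    trend_cfg=None,
    n_max: int = 30,
    variogram_cfg: dict | None = None,
    allow_small_n: bool = False,
) -> HybridModel:
    """Three-step hybrid construction: trend fit, residuals, residual variogram.

    ``variogram_cfg`` may carry ``n_bins`` and ``cutoff`` for the empirical
    residual variogram (defaults: 15 bins, cutoff one-third of the maximum
    pairwise distance).
    """
    check_sample_size(data.n, data.p, override=allow_small_n)
    if trend_kind == "brt":
        trend = fit_brt(data, trend_cfg or BRTConfig())
    elif trend_kind == "lasso":
        cfg = trend_cfg or LassoConfig()
        trend = fit_lasso(data, penalty=cfg.penalty, tol=cfg.tol, max_iter=cfg.max_iter)
    else:
        raise DataValidationError(f"unknown trend kind {trend_kind!r}")
    residuals = data.target - predict_trend(trend, data.covariates)
    vcfg = variogram_cfg or {}
    ev = empirical_variogram(
        (data.coords, residuals),
        n_bins=vcfg.get("n_bins", 15),
        cutoff=vcfg.get("cutoff"),
    )
    vm = fit_spherical(ev)
    return HybridModel(
        trend=trend,
        residual_variogram=vm,
        train_coords=data.coords,
        train_residuals=residuals,
        n_max=int(n_max),
    )


def predict_hybrid(model: HybridModel, X_new, coords_new, return_variance: bool = False):
    """Hybrid prediction: trend at the new covariates plus kriged residuals.

    Exactly the sum of ``predict_trend`` and ``krige_grid`` on the stored
    residual field; with ``return_variance`` the residual-kriging variances are
    returned alongside (the trend contributes no uncertainty term).
    """
    coords_new = np.asarray(coords_new, dtype=float)
    if coords_new.ndim != 2 or coords_new.shape[1] != 2:
        raise DataValidationError("coords_new must be an (m, 2) array")
    m_hat = predict_trend(model.trend, X_new)
    if m_hat.shape[0] != coords_new.shape[0]:
        raise DataValidationError("X_new and coords_new row counts differ")
    out = krige_grid(
        (model.train_coords, model.train_residuals),
        model.residual_variogram,
        coords_new,
        model.n_max,
        return_variance=return_variance,
    )
    if return_variance:
        e_hat, var = out
        return m_hat + e_hat, var
    return m_hat + out
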