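"""Point-referenced spatial datasets.

The central container is :class:`SpatialDataset`: ``n`` planar locations, a
continuous response ``y(x_i)`` and an ``n x p`` covariate matrix (``p = 0`` is
legal for kriging-only use).  CSV input/output goes through pandas and uses a
plain comma-separated dialect with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = ["SpatialDataset"]


def _as_2d(a, name, ncol=None):
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise DataValidationError(f"{name} must be 2-dimensional, got ndim={arr.ndim}")
    if ncol is not None and arr.shape[1] != ncol:
        raise DataValidationError(f"{name} must have {ncol} columns, got {arr.shape[1]}")
    return arr


@dataclass(frozen=True)
class SpatialDataset:
    """Immutable bundle of coordinates, response and covariates.

    Parameters
    ----------
    coords
        ``(n, 2)`` planar coordinates.  Distances are plain Euclidean on these
        columns; latitude/longitude are treated as planar degrees.
    target
        Length-``n`` response vector, one value per location.
    covariates
        ``(n, p)`` matrix of continuous covariates; ``p = 0`` allowed.
    covariate_names
        ``p`` column labels, unique.
    allow_duplicate_coords
        Duplicate locations are rejected unless this flag is set (kriging
        systems built from exact duplicates are singular when the nugget is
        zero).  Use :meth:`average_duplicates` to collapse them instead.
    """

    coords: np.ndarray
    target: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())
    allow_duplicate_coords: bool = False

    def __post_init__(self):
        coords = _as_2d(self.coords, "coords", ncol=2)
        target = np.asarray(self.target, dtype=float).ravel()
        n = coords.shape[0]
        if n < 1:
            raise DataValidationError("dataset must contain at least one point")
        if target.shape[0] != n:
            raise DataValidationError(
                f"target length {target.shape[0]} does not match n={n} locations"
            )
        cov = self.covariates
        if cov is None:
            cov = np.empty((n, 0))
        cov = _as_2d(cov, "covariates")
        if cov.shape[0] != n:
            raise DataValidationError(
                f"covariates have {cov.shape[0]} rows, expected n={n}"
            )
        names = tuple(self.covariate_names)
        if not names and cov.shape[1] > 0:
            names = tuple(f"v{j + 1}" for j in range(cov.shape[1]))
        if len(names) != cov.shape[1]:
            raise DataValidationError(
                f"{len(names)} covariate names for {cov.shape[1]} covariate columns"
            )
        if len(set(names)) != len(names):
            raise DataValidationError("covariate names must be unique")
        for arr, label in ((coords, "coords"), (target, "target"), (cov, "covariates")):
            if not np.all(np.isfinite(arr)):
                raise DataValidationError(f"{label} contain non-finite values")
        if not self.allow_duplicate_coords and n > 1:
            uniq = np.unique(coords, axis=0)
            if uniq.shape[0] != n:
                raise DataValidationError(
                    "duplicate coordinates present; pass allow_duplicate_coords=True "
                    "or collapse them with average_duplicates()"
                )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx) -> "SpatialDataset":
        """Row subset (any numpy fancy index), preserving covariate names."""
        idx = np.asarray(idx)
        return replace(
            self,
            coords=self.coords[idx],
            target=self.target[idx],
            covariates=self.covariates[idx],
        )

    def drop_covariates(self, names) -> "SpatialDataset":
        """Remove covariate columns by name; unknown names raise."""
        names = list(names)
        unknown = sorted(set(names) - set(self.covariate_names))
        if unknown:
            raise DataValidationError(f"unknown covariate names: {unknown}")
        keep = [j for j, nm in enumerate(self.covariate_names) if nm not in names]
        return replace(
            self,
            covariates=self.covariates[:, keep],
            covariate_names=tuple(self.covariate_names[j] for j in keep),
        )

    def with_target(self, target) -> "SpatialDataset":
        return replace(self, target=np.asarray(target, dtype=float))

    def average_duplicates(self) -> "SpatialDataset":
        """Collapse exactly coincident locations, averaging response and covariates."""
        uniq, inverse = np.unique(self.coords, axis=0, return_inverse=True)
        m = uniq.shape[0]
        counts = np.bincount(inverse, minlength=m).astype(float)
        target = np.bincount(inverse, weights=self.target, minlength=m) / counts
        cov = np.empty((m, self.p))
        for j in range(self.p):
            cov[:, j] = (
                np.bincount(inverse, weights=self.covariates[:, j], minlength=m) / counts
            )
        return SpatialDataset(uniq, target, cov, self.covariate_names)

    # ------------------------------------------------------------------ I/O

    def to_frame(self, x_col="x", y_col="y", target_col="response") -> pd.DataFrame:
        df = pd.DataFrame({x_col: self.coords[:, 0], y_col: self.coords[:, 1]})
        df[target_col] = self.target
        for j, nm in enumerate(self.covariate_names):
            df[nm] = self.covariates[:, j]
        return df

    def to_csv(self, path, x_col="x", y_col="y", target_col="response") -> None:
        self.to_frame(x_col, y_col, target_col).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        x_col="x",
        y_col="y",
        target_col="response",
        covariate_cols=None,
        drop_na=False,
        allow_duplicate_coords=False,
    ) -> "SpatialDataset":
        """Read a header-ed CSV of points.

        ``covariate_cols=None`` takes every column that is not a coordinate or
        the response.  ``drop_na`` removes incomplete rows (the count is
        recorded in the ``n_dropped`` attribute of the returned frame's source);
        without it any missing value is an error.
        """
        df = pd.read_csv(path)
        for col in (x_col, y_col, target_col):
            if col not in df.columns:
                raise DataValidationError(f"column {col!r} not found in {path}")
        if covariate_cols is None:
            covariate_cols = [
                c for c in df.columns if c not in (x_col, y_col, target_col)
            ]
        else:
            missing = [c for c in covariate_cols if c not in df.columns]
            if missing:
                raise DataValidationError(f"covariate columns not found: {missing}")
        used = [x_col, y_col, target_col, *covariate_cols]
        sub = df[used]
        if drop_na:
            sub = sub.dropna(axis=0)
        elif sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise DataValidationError(
                f"missing values in columns {bad}; pass drop_na=True to discard rows"
            )
        ds = cls(
            coords=sub[[x_col, y_col]].to_numpy(dtype=float),
            target=sub[target_col].to_numpy(dtype=float),
            covariates=sub[covariate_cols].to_numpy(dtype=float)
            if covariate_cols
            else np.empty((len(sub), 0)),
            covariate_names=tuple(covariate_cols),
            allow_duplicate_coords=allow_duplicate_coords,
        )
        object.__setattr__(ds, "n_dropped", len(df) - len(sub))
        return ds
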