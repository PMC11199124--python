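"""Variography and local-neighborhood ordinary kriging.

Ordinary kriging (OK) predicts the field at a new location ``x0`` as a weighted
sum of nearby observations, ``y_hat(x0) = sum_i lambda_i y(x_i)``, with the
weights chosen to minimise the prediction variance subject to the unbiasedness
constraint ``sum_i lambda_i = 1``.  The weights solve a linear system built
from the semivariogram ``gamma(h)``, here always the spherical model

    gamma(h) = c0 + c1 * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    gamma(h) = c0 + c1                              for h > a
    gamma(0) = 0

with nugget ``c0``, partial sill ``c1`` and range ``a``.  Only the ``nMax``
nearest observations enter each prediction (the "searching window"), which
keeps the solve local and cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .data import SpatialDataset
from .errors import DataValidationError, KrigingError, VariogramFitError

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "KrigingPrediction",
    "empirical_variogram",
    "fit_spherical",
    "krige_point",
    "krige_grid",
]


def _point_values(data):
    """Accept a SpatialDataset or a ``(coords, values)`` pair of arrays."""
    if isinstance(data, SpatialDataset):
        return data.coords, data.target
    coords, values = data
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise DataValidationError("coords must be an (n, 2) array")
    if values.shape[0] != coords.shape[0]:
        raise DataValidationError("values length does not match coords")
    return coords, values


# --------------------------------------------------------------------- types


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron semivariance estimates.

    Bins with no pairs are dropped, so ``lag_centers`` is strictly increasing
    and every ``pair_counts`` entry is positive.
    """

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    cutoff: float

    def __post_init__(self):
        lags = np.asarray(self.lag_centers, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        counts = np.asarray(self.pair_counts, dtype=int)
        if not (lags.shape == g.shape == counts.shape):
            raise DataValidationError("variogram component lengths differ")
        if np.any(np.diff(lags) <= 0):
            raise DataValidationError("lag_centers must be strictly increasing")
        if np.any(g < 0) or np.any(counts <= 0):
            raise DataValidationError("gamma must be >= 0 and pair_counts positive")
        object.__setattr__(self, "lag_centers", lags)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "pair_counts", counts)

    @property
    def n_bins(self) -> int:
        return self.lag_centers.shape[0]


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram: nugget ``c0``, partial sill ``c1``, range ``a``."""

    nugget: float
    partial_sill: float
    range_a: float
    model_name: str = "spherical"

    def __post_init__(self):
        if self.model_name != "spherical":
            raise DataValidationError("only the spherical model is supported")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_a <= 0:
            raise DataValidationError(
                "require nugget >= 0, partial_sill >= 0, range_a > 0"
            )

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h):
        """Semivariance at lag(s) ``h``; gamma(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        r = np.minimum(h / self.range_a, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * r - 0.5 * r**3)
        return np.where(h > 0, g, 0.0)

    def covariance(self, h):
        """Stationary covariance C(h) = sill - gamma(h) for h > 0, sill at h = 0."""
        h = np.asarray(h, dtype=float)
        return np.where(h > 0, self.sill - self.gamma(h), self.sill)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range_a": self.range_a,
        }

    @classmethod
    def from_dict(cls, d) -> "VariogramModel":
        return cls(
            nugget=float(d["nugget"]),
            partial_sill=float(d["partial_sill"]),
            range_a=float(d["range_a"]),
            model_name=d.get("model_name", "spherical"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class KrigingPrediction:
    value: float
    variance: float
    weights: np.ndarray
    neighbor_indices: np.ndarray


# ---------------------------------------------------------- empirical gamma


def empirical_variogram(data, n_bins: int = 15, cutoff: float | None = None) -> EmpiricalVariogram:
    """Binned Matheron semivariogram estimator.

    For each distance bin ``b`` with pair set ``N(h_b)``:
    ``gamma_hat(h_b) = sum_{(i,j) in N(h_b)} (y_i - y_j)^2 / (2 |N(h_b)|)``.

    Pairs farther apart than ``cutoff`` are excluded; the default cutoff is
    one-third of the maximum pairwise distance, split into ``n_bins``
    equal-width bins.  Empty bins are dropped.
    """
    coords, values = _point_values(data)
    n = coords.shape[0]
    if n < 2:
        raise DataValidationError("empirical variogram needs at least 2 points")
    if n_bins < 1:
        raise DataValidationError("n_bins must be >= 1")
    d = pdist(coords)
    if cutoff is None:
        cutoff = d.max() / 3.0
    if cutoff <= 0:
        raise DataValidationError("cutoff must be > 0")
    keep = (d > 0) & (d <= cutoff)
    if not np.any(keep):
        raise DataValidationError("no lag pairs: all pairwise distances exceed the cutoff")
    d = d[keep]
    dv = pdist(values[:, None])[keep]  # |y_i - y_j| per pair, same ordering
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dv**2, minlength=n_bins)
    nonempty = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_centers=centers[nonempty],
        gamma=sums[nonempty] / (2.0 * counts[nonempty]),
        pair_counts=counts[nonempty],
        cutoff=float(cutoff),
    )


# ------------------------------------------------------------ model fitting


def _spherical_gamma(h, c0, c1, a):
    r = np.minimum(h / a, 1.0)
    return c0 + c1 * (1.5 * r - 0.5 * r**3)


def fit_spherical(ev: EmpiricalVariogram, init: VariogramModel | None = None) -> VariogramModel:
    """Weighted least-squares fit of the spherical model.

    Minimises ``sum_b w_b (gamma_hat_b - gamma(h_b; c0, c1, a))^2`` with the
    gstat-style weights ``w_b = N_b / h_b^2``, subject to ``c0, c1 >= 0`` and
    ``a`` above a tiny lower bound.  Several starting points are tried and the
    lowest-cost solution kept; a fit that collapses to pure nugget is reported
    with the range at its lower search bound for determinism.
    """
    if ev.n_bins < 3:
        raise VariogramFitError("need at least 3 non-empty bins to fit 3 parameters")
    h = ev.lag_centers
    g = ev.gamma
    if np.all(g == 0):
        raise VariogramFitError(
            "degenerate empirical variogram: all semivariances are zero "
            "(constant field?)"
        )
    sw = np.sqrt(ev.pair_counts / h**2)
    a_lo = max(h[0] * 1e-3, 1e-12)

    def residuals(theta):
        c0, c1, a = theta
        return sw * (g - _spherical_gamma(h, c0, c1, a))

    gmax = float(g.max())
    gmin = float(g.min())
    starts = [
        (0.0, gmax, ev.cutoff / 2.0),
        (gmin, max(gmax - gmin, 1e-8 * gmax), ev.cutoff / 4.0),
        (0.5 * gmin, gmax, 0.9 * ev.cutoff),
    ]
    if init is not None:
        starts.insert(0, (init.nugget, init.partial_sill, max(init.range_a, a_lo)))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals,
                x0=np.maximum(x0, [0.0, 0.0, a_lo]),
                bounds=([0.0, 0.0, a_lo], [np.inf, np.inf, np.inf]),
                method="trf",
            )
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise VariogramFitError("spherical variogram fit failed from every start")
    c0, c1, a = best.x
    r = min(ev.cutoff / a, 1.0)
    struct_at_cutoff = c1 * (1.5 * r - 0.5 * r**3)
    if struct_at_cutoff <= 1e-8 * max(c0 + c1, 1e-300):
        # pure-nugget limit: structured part negligible over all observed lags,
        # the range is unidentifiable — fold it into the nugget, pin a low
        c0, c1, a = c0 + struct_at_cutoff, 0.0, a_lo
    return VariogramModel(nugget=float(c0), partial_sill=float(c1), range_a=float(a))


# ------------------------------------------------------------------ kriging


def _solve_ok(nb_coords, nb_values, vm, x0):
    """Solve the bordered ordinary-kriging system for one target location."""
    k = nb_coords.shape[0]
    diff = nb_coords[:, None, :] - nb_coords[None, :, :]
    dmat = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    A = np.empty((k + 1, k + 1))
    A[:k, :k] = vm.gamma(dmat)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    A[k, k] = 0.0
    d0 = np.sqrt(((nb_coords - x0) ** 2).sum(axis=1))
    b = np.empty(k + 1)
    b[:k] = vm.gamma(d0)
    b[k] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise KrigingError(f"singular kriging system: {exc}") from exc
    lam, mu = sol[:k], sol[k]
    value = float(lam @ nb_values)
    variance = float(lam @ b[:k] + mu)
    if variance < -1e-8:
        raise KrigingError(f"negative kriging variance {variance:.3e}")
    variance = max(variance, 0.0)
    return value, variance, lam


def _check_neighbor_duplicates(nb_coords, nb_idx):
    uniq, inverse, counts = np.unique(
        nb_coords, axis=0, return_inverse=True, return_counts=True
    )
    if uniq.shape[0] == nb_coords.shape[0]:
        return
    dup_groups = [
        sorted(np.asarray(nb_idx)[inverse == g].tolist())
        for g in np.flatnonzero(counts > 1)
    ]
    raise KrigingError(
        f"duplicate neighbor locations at training indices {dup_groups}; "
        "deduplicate the training data first"
    )


def _neighbors(coords, x0, n_max):
    # stable argsort on distances breaks exact-distance ties by ascending index
    k = min(n_max, coords.shape[0])
    d = np.sqrt(((coords - x0) ** 2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:k]
    return np.sort(idx)


def krige_point(train, vm: VariogramModel, x0, n_max: int) -> KrigingPrediction:
    """Ordinary-kriging prediction at ``x0`` from the ``n_max`` nearest points.

    Neighbors are selected by Euclidean distance with ties broken by ascending
    row index.  Returns the predicted value, the kriging variance and the
    weights (which sum to one by construction of the bordered system).
    """
    coords, values = _point_values(train)
    if n_max < 1:
        raise DataValidationError("n_max must be >= 1")
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.shape[0] != 2:
        raise DataValidationError("x0 must be a length-2 location")
    idx = _neighbors(coords, x0, n_max)
    nb_coords, nb_values = coords[idx], values[idx]
    _check_neighbor_duplicates(nb_coords, idx)
    value, variance, lam = _solve_ok(nb_coords, nb_values, vm, x0)
    return KrigingPrediction(
        value=value, variance=variance, weights=lam, neighbor_indices=idx
    )


def krige_grid(train, vm: VariogramModel, targets, n_max: int, return_variance: bool = False):
    """Kriging at many target locations; elementwise identical to krige_point.

    Every target goes through the same neighbor search and single-point solver
    as :func:`krige_point`, so results match a scalar loop exactly.
    """
    coords, values = _point_values(train)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape[1] != 2:
        raise DataValidationError("targets must be an (m, 2) array")
    if n_max < 1:
        raise DataValidationError("n_max must be >= 1")
    preds = np.empty(targets.shape[0])
    variances = np.empty(targets.shape[0])
    for i, x0 in enumerate(targets):
        idx = _neighbors(coords, x0, n_max)
        nb_coords = coords[idx]
        try:
            _check_neighbor_duplicates(nb_coords, idx)
            preds[i], variances[i], _ = _solve_ok(nb_coords, values[idx], vm, x0)
        except KrigingError as exc:
            raise KrigingError(f"target {i} at {tuple(x0)}: {exc}") from exc
    if return_variance:
        return preds, variances
    return preds
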