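"""Synthetic spatial datasets with the structure the hybrid method assumes.

Each dataset is response = trend(covariates) + spatially correlated residual +
white noise, on uniformly random locations in the unit square:

- covariates are i.i.d. standard normal (optionally sharing a latent factor to
  emulate the multicollinearity typical of ecological covariate suites);
- the trend is either sparse-linear or nonlinear (additive smooth terms plus
  one pairwise interaction) in a small active subset of covariates;
- the residual field is a zero-mean Gaussian random field whose covariance
  follows a spherical variogram, drawn by dense Cholesky factorisation (which
  caps n at desk scale, a few thousand points).

The generating truth (active set, effect sizes, variogram parameters, noise
level) is returned alongside the data so recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import SpatialDataset
from .errors import DataValidationError, NumericalError
from .geostat import VariogramModel

__all__ = ["SimSpec", "simulate_grf", "make_dataset"]

_MAX_DENSE_N = 3000


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one synthetic dataset; identical specs give identical data.

    Defaults are the package's benchmark conditions: n = 800 points in the
    unit square, p = 10 covariates of which 3 are active, a nonlinear trend
    with one interaction, spherical residual field (c0 = 0.1, c1 = 0.5,
    a = 0.3 — a range an order of magnitude above the typical nearest-neighbor
    spacing, so residual kriging has real structure to exploit) and white
    noise of sd 0.2.
    """

    n: int = 800
    p: int = 10
    trend_kind: str = "nonlinear-interaction"  # or "linear-sparse"
    active: tuple[int, ...] = (0, 1, 2)
    effects: tuple[float, ...] = (1.0, 0.7, 0.5)
    interaction_effect: float = 0.5
    nugget: float = 0.1
    partial_sill: float = 0.5
    range_a: float = 0.3
    noise_sd: float = 0.2
    covariate_correlation: float = 0.0
    domain: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.p < 0:
            raise DataValidationError("need n >= 1 and p >= 0")
        if self.n > _MAX_DENSE_N:
            raise DataValidationError(
                f"n={self.n} exceeds the dense-Cholesky cap ({_MAX_DENSE_N})"
            )
        if self.trend_kind not in ("linear-sparse", "nonlinear-interaction"):
            raise DataValidationError(f"unknown trend kind {self.trend_kind!r}")
        if len(self.active) != len(self.effects):
            raise DataValidationError("active set and effects must have equal length")
        if any(j < 0 or j >= self.p for j in self.active):
            raise DataValidationError("active indices must lie in [0, p)")
        if not 0 <= self.covariate_correlation < 1:
            raise DataValidationError("covariate_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be >= 0")

    @property
    def variogram(self) -> VariogramModel:
        return VariogramModel(
            nugget=self.nugget, partial_sill=self.partial_sill, range_a=self.range_a
        )


def simulate_grf(coords, vm: VariogramModel, seed: int = 0) -> np.ndarray:
    """Zero-mean Gaussian field with spherical-variogram covariance.

    Covariance is ``C(h) = sill - gamma(h)`` for ``h > 0`` and the full sill on
    the diagonal (the nugget enters as spatially white variance).  Drawn by
    dense Cholesky with a 1e-10 diagonal jitter retry if the factorisation
    fails.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n > _MAX_DENSE_N:
        raise DataValidationError(f"n={n} exceeds the dense-Cholesky cap")
    dmat = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    cov = vm.covariance(dmat)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        try:
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "residual covariance not positive definite even after 1e-10 jitter"
            ) from exc
    z = np.random.default_rng(seed).standard_normal(n)
    return chol @ z


def _trend_values(spec: SimSpec, X: np.ndarray) -> np.ndarray:
    out = np.zeros(X.shape[0])
    active = list(spec.active)
    effects = list(spec.effects)
    if spec.trend_kind == "linear-sparse":
        for j, eff in zip(active, effects):
            out += eff * X[:, j]
        return out
    # nonlinear-interaction: smooth additive main effects (linear, centered
    # quadratic, saturating) plus one pairwise interaction of the first two
    shapes = [lambda v: v, lambda v: v**2 - 1.0, np.tanh]
    for i, (j, eff) in enumerate(zip(active, effects)):
        out += eff * shapes[i % len(shapes)](X[:, j])
    if len(active) >= 2 and spec.interaction_effect != 0.0:
        out += spec.interaction_effect * X[:, active[0]] * X[:, active[1]]
    return out


def make_dataset(spec: SimSpec):
    """Draw one dataset from the spec; returns (SpatialDataset, truth record).

    The truth record carries everything needed for recovery tests: the spec
    itself, the noiseless trend values, the residual-field draw and the
    effective nugget (spec nugget plus white-noise variance) a residual
    variogram should see.
    """
    rng = np.random.default_rng(spec.seed)
    x0, x1, y0, y1 = spec.domain
    coords = np.column_stack(
        [rng.uniform(x0, x1, spec.n), rng.uniform(y0, y1, spec.n)]
    )
    X = rng.standard_normal((spec.n, spec.p))
    if spec.covariate_correlation > 0 and spec.p > 1:
        rho = spec.covariate_correlation
        factor = rng.standard_normal((spec.n, 1))
        X = np.sqrt(rho) * factor + np.sqrt(1 - rho) * X
    trend = _trend_values(spec, X)
    grf_seed = int(rng.integers(0, 2**31 - 1))
    grf = simulate_grf(coords, spec.variogram, seed=grf_seed)
    noise = spec.noise_sd * rng.standard_normal(spec.n)
    data = SpatialDataset(
        coords=coords,
        target=trend + grf + noise,
        covariates=X,
        covariate_names=tuple(f"v{j + 1}" for j in range(spec.p)),
    )
    truth = {
        "spec": asdict(spec),
        "trend": trend,
        "grf": grf,
        "grf_seed": grf_seed,
        "effective_nugget": spec.nugget + spec.noise_sd**2,
        "sill": spec.nugget + spec.partial_sill,
        "active_names": [f"v{j + 1}" for j in spec.active],
    }
    return data, truth


def truth_to_json(truth: dict) -> str:
    """Serializable sidecar: the truth record minus the bulky per-point draws."""
    slim = {k: v for k, v in truth.items() if k not in ("trend", "grf")}
    return json.dumps(slim, indent=2)
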