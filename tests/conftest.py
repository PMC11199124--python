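import numpy as np
import pytest

from resok import SimSpec, SpatialDataset, make_dataset


@pytest.fixture(scope="session")
def benchmark():
    """Default benchmark dataset: n=800, p=10, nonlinear trend + spherical field."""
    data, truth = make_dataset(SimSpec(seed=7))
    return data, truth


@pytest.fixture(scope="session")
def small_linear():
    """Small sparse-linear dataset for quick model checks."""
    spec = SimSpec(
        n=150,
        p=5,
        trend_kind="linear-sparse",
        active=(0, 2),
        effects=(1.0, -0.8),
        partial_sill=0.3,
        range_a=0.25,
        noise_sd=0.2,
        seed=11,
    )
    data, truth = make_dataset(spec)
    return data, truth


@pytest.fixture()
def random_points():
    """Irregular scatter with a smooth deterministic surface, no model truth."""
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 1, size=(40, 2))
    values = np.sin(3 * coords[:, 0]) + coords[:, 1] ** 2 + 0.1 * rng.standard_normal(40)
    return coords, values


def make_linear_dataset(n=80, p=4, seed=0, noise=0.0, coef=None, intercept=2.0):
    """Pure covariate-driven dataset: y = b0 + X @ coef + noise, random coords."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    coef = np.asarray(coef if coef is not None else np.linspace(1.0, 0.2, p))
    y = intercept + X @ coef + noise * rng.standard_normal(n)
    coords = rng.uniform(0, 1, size=(n, 2))
    return SpatialDataset(coords, y, X), coef
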