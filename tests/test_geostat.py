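"""Empirical variography, spherical fitting and ordinary kriging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resok import (
    DataValidationError,
    EmpiricalVariogram,
    KrigingError,
    VariogramFitError,
    VariogramModel,
    empirical_variogram,
    fit_spherical,
    krige_grid,
    krige_point,
)


def brute_force_variogram(coords, values, n_bins, cutoff):
    """Independent O(n^2) pair-enumeration Matheron estimator."""
    n = len(values)
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(coords[i] - coords[j]))
            if d <= 0 or d > cutoff:
                continue
            b = min(int(np.searchsorted(edges, d, side="left")) - 1, n_bins - 1)
            b = max(b, 0)
            sums[b] += (values[i] - values[j]) ** 2
            counts[b] += 1
    keep = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[keep], sums[keep] / (2 * counts[keep]), counts[keep]


class TestEmpiricalVariogram:
    def test_two_points_single_bin(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        ev = empirical_variogram((coords, [0.0, 2.0]), n_bins=1, cutoff=1.5)
        assert ev.gamma == pytest.approx([2.0])
        assert ev.pair_counts.tolist() == [1]

    def test_constant_field_zero_everywhere(self, random_points):
        coords, _ = random_points
        ev = empirical_variogram((coords, np.full(len(coords), 3.7)))
        assert np.all(ev.gamma == 0.0)

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1, size=(50, 2))
        values = rng.standard_normal(50)
        cutoff = 0.5
        ev = empirical_variogram((coords, values), n_bins=12, cutoff=cutoff)
        centers, gamma, counts = brute_force_variogram(coords, values, 12, cutoff)
        assert ev.lag_centers == pytest.approx(centers, abs=1e-12)
        assert ev.gamma == pytest.approx(gamma, abs=1e-12)
        assert ev.pair_counts.tolist() == counts.tolist()

    def test_all_pairs_beyond_cutoff_errors(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        with pytest.raises(DataValidationError, match="no lag pairs"):
            empirical_variogram((coords, [0.0, 1.0]), cutoff=1.0)

    def test_single_point_errors(self):
        with pytest.raises(DataValidationError):
            empirical_variogram((np.zeros((1, 2)), [1.0]))

    def test_default_cutoff_is_third_of_max_distance(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
        ev = empirical_variogram((coords, [0.0, 1.0, 2.0]), n_bins=3)
        assert ev.cutoff == pytest.approx(1.0)


class TestFitSpherical:
    def test_noiseless_self_consistency(self):
        truth = VariogramModel(nugget=0.0, partial_sill=1.0, range_a=0.5)
        lags = np.linspace(0.05, 0.95, 10)
        ev = EmpiricalVariogram(
            lag_centers=lags,
            gamma=truth.gamma(lags),
            pair_counts=np.full(10, 50),
            cutoff=1.0,
        )
        fit = fit_spherical(ev)
        assert fit.nugget == pytest.approx(0.0, abs=1e-6)
        assert fit.partial_sill == pytest.approx(1.0, abs=1e-6)
        assert fit.range_a == pytest.approx(0.5, abs=1e-6)

    def test_pure_nugget_limit(self):
        level = 2.0
        ev = EmpiricalVariogram(
            lag_centers=np.linspace(0.1, 1.0, 8),
            gamma=np.full(8, level),
            pair_counts=np.full(8, 20),
            cutoff=1.0,
        )
        fit = fit_spherical(ev)
        assert fit.sill == pytest.approx(level, abs=1e-6)
        # the structured part is flat over all observed lags
        assert fit.gamma(ev.lag_centers) == pytest.approx(np.full(8, level), abs=1e-6)

    def test_degenerate_all_zero_errors(self):
        ev = EmpiricalVariogram(
            lag_centers=np.linspace(0.1, 1.0, 5),
            gamma=np.zeros(5),
            pair_counts=np.full(5, 9),
            cutoff=1.0,
        )
        with pytest.raises(VariogramFitError, match="degenerate"):
            fit_spherical(ev)

    def test_too_few_bins_errors(self):
        ev = EmpiricalVariogram(
            lag_centers=np.array([0.1, 0.2]),
            gamma=np.array([0.5, 0.9]),
            pair_counts=np.array([4, 4]),
            cutoff=0.3,
        )
        with pytest.raises(VariogramFitError):
            fit_spherical(ev)


class TestSphericalModel:
    def test_shape_invariants(self):
        vm = VariogramModel(nugget=0.2, partial_sill=1.0, range_a=0.4)
        h = np.linspace(0, 1, 200)
        g = vm.gamma(h)
        assert g[0] == 0.0
        assert np.all(np.diff(g) >= -1e-12)  # nondecreasing
        assert np.all(g[h >= 0.4] == pytest.approx(1.2))  # exactly sill past range
        assert vm.covariance(0.0) == pytest.approx(1.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DataValidationError):
            VariogramModel(nugget=-0.1, partial_sill=1.0, range_a=0.5)
        with pytest.raises(DataValidationError):
            VariogramModel(nugget=0.0, partial_sill=1.0, range_a=0.5, model_name="gaussian")

    def test_serialization_round_trip(self):
        vm = VariogramModel(nugget=0.05, partial_sill=0.8, range_a=0.31)
        assert VariogramModel.from_dict(vm.to_dict()) == vm

    @settings(deadline=None, derandomize=True)
    @given(
        c0=st.floats(0.0, 10.0),
        c1=st.floats(0.0, 10.0),
        a=st.floats(1e-3, 10.0),
    )
    def test_model_invariants_hold_for_any_parameters(self, c0, c1, a):
        vm = VariogramModel(nugget=c0, partial_sill=c1, range_a=a)
        h = np.linspace(0.0, 2 * a, 101)
        g = vm.gamma(h)
        assert g[0] == 0.0
        assert np.all(np.diff(g) >= -1e-9)
        assert np.all(np.abs(g[h >= a] - vm.sill) < 1e-12)
        assert np.all(vm.covariance(h[1:]) == pytest.approx(vm.sill - g[1:]))


VM = VariogramModel(nugget=0.0, partial_sill=1.0, range_a=0.5)


def dense_global_krige(coords, values, vm, x0):
    """Oracle: direct solve of the full bordered kriging system on all points."""
    n = len(values)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = vm.gamma(np.hypot(*(coords[i] - coords[j])))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.ones(n + 1)
    b[:n] = vm.gamma(np.hypot(coords[:, 0] - x0[0], coords[:, 1] - x0[1]))
    sol = np.linalg.solve(A, b)
    return float(sol[:n] @ values)


class TestKrigePoint:
    def test_single_training_point(self):
        pred = krige_point((np.array([[0.3, 0.3]]), [4.2]), VM, (0.9, 0.1), n_max=10)
        assert pred.value == pytest.approx(4.2)
        assert pred.weights == pytest.approx([1.0])

    def test_exact_interpolation_zero_nugget(self, random_points):
        coords, values = random_points
        for i in (0, 7, 23):
            pred = krige_point((coords, values), VM, coords[i], n_max=len(values))
            assert pred.value == pytest.approx(values[i], abs=1e-8)
            assert pred.variance <= 1e-8

    def test_symmetric_pair_gets_equal_weights(self):
        coords = np.array([[-1.0, 0.0], [1.0, 0.0]])
        pred = krige_point((coords, [2.0, 6.0]), VM, (0.0, 0.0), n_max=2)
        assert pred.weights == pytest.approx([0.5, 0.5], abs=1e-12)
        assert pred.value == pytest.approx(4.0)

    def test_local_equals_dense_global_solve(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 1, size=(25, 2))
        values = rng.standard_normal(25)
        vm = VariogramModel(nugget=0.1, partial_sill=0.9, range_a=0.4)
        for x0 in rng.uniform(0, 1, size=(6, 2)):
            pred = krige_point((coords, values), vm, x0, n_max=25)
            assert pred.value == pytest.approx(
                dense_global_krige(coords, values, vm, x0), abs=1e-8
            )

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 1, size=(60, 2))
        values = rng.standard_normal(60)
        vm = VariogramModel(nugget=0.3, partial_sill=0.7, range_a=0.2)
        for x0 in rng.uniform(0, 1, size=(20, 2)):
            for n_max in (1, 5, 30, 200):
                pred = krige_point((coords, values), vm, x0, n_max=n_max)
                assert abs(pred.weights.sum() - 1.0) < 1e-10

    def test_duplicate_neighbors_error_names_indices(self):
        coords = np.array([[0.0, 0.0], [0.5, 0.5], [0.5, 0.5], [1.0, 1.0]])
        with pytest.raises(KrigingError, match=r"\[1, 2\]"):
            krige_point((coords, [1.0, 2.0, 3.0, 4.0]), VM, (0.4, 0.4), n_max=4)

    def test_neighbor_count_capped_by_n(self, random_points):
        coords, values = random_points
        pred = krige_point((coords, values), VM, (0.5, 0.5), n_max=1000)
        assert len(pred.neighbor_indices) == len(values)
        pred = krige_point((coords, values), VM, (0.5, 0.5), n_max=7)
        assert len(pred.neighbor_indices) == 7


class TestKrigeGrid:
    def test_single_target_equals_point(self, random_points):
        coords, values = random_points
        x0 = np.array([0.42, 0.17])
        grid_pred = krige_grid((coords, values), VM, x0[None, :], n_max=10)
        assert grid_pred[0] == krige_point((coords, values), VM, x0, n_max=10).value

    def test_training_targets_reproduce_values(self, random_points):
        coords, values = random_points
        preds = krige_grid((coords, values), VM, coords, n_max=15)
        assert preds == pytest.approx(values, abs=1e-8)

    def test_equals_scalar_loop_exactly(self, random_points):
        coords, values = random_points
        rng = np.random.default_rng(0)
        targets = rng.uniform(0, 1, size=(100, 2))
        vm = VariogramModel(nugget=0.05, partial_sill=0.6, range_a=0.3)
        grid_preds, grid_vars = krige_grid(
            (coords, values), vm, targets, n_max=12, return_variance=True
        )
        for i, x0 in enumerate(targets):
            pred = krige_point((coords, values), vm, x0, n_max=12)
            assert grid_preds[i] == pred.value  # bitwise: same code path
            assert grid_vars[i] == pred.variance

    def test_error_carries_target_context(self):
        coords = np.array([[0.5, 0.5], [0.5, 0.5], [0.2, 0.2]])
        with pytest.raises(KrigingError, match="target 0"):
            krige_grid((coords, [1.0, 2.0, 3.0]), VM, np.array([[0.4, 0.4]]), n_max=3)
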