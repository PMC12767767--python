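"""Gaussian mixture model, GoF metrics, sequential bounds, multi-start fits."""

import math

import numpy as np
import pytest

from diffsizer import (
    GaussianComponent,
    fit_mixture,
    gof_metrics,
    mixture_value,
    sequential_sigma_bounds,
)
from diffsizer.errors import DomainError, InfeasibleBoundsError
from diffsizer.mixturefit import MixtureFit, order_scan


def grid_search_single_gaussian(x, y, a_grid, b_grid, c_grid):
    """Independent brute-force oracle: best (a, b, c) node by SSE."""
    best, best_sse = None, np.inf
    for a in a_grid:
        for b in b_grid:
            for c in c_grid:
                resid = y - a * np.exp(-(((x - b) / c) ** 2))
                sse = float(resid @ resid)
                if sse < best_sse:
                    best, best_sse = (a, b, c), sse
    return best, best_sse


class TestMixtureValue:
    def test_peak_and_e_folding(self):
        comp = [GaussianComponent(100.0, 0.0, 10.0)]
        assert mixture_value(comp, 0.0) == pytest.approx(100.0)
        # at x = c the value falls to a/e (no factor 2 in the exponent)
        assert mixture_value(comp, 10.0) == pytest.approx(100.0 / math.e, rel=1e-12)

    def test_linearity(self):
        comp = GaussianComponent(50.0, 1.0, 8.0)
        x = np.linspace(-30, 30, 61)
        np.testing.assert_allclose(
            mixture_value([comp, comp], x), 2 * mixture_value([comp], x), rtol=1e-14
        )


class TestGoF:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 2.0])
        g = gof_metrics(y, y, p=3)
        assert g.sse == 0.0 and g.rmse == 0.0 and g.r2 == 1.0

    def test_hand_computed_rmse(self):
        obs = np.array([1.0, -1.0, 1.0, -1.0])
        g = gof_metrics(obs, np.zeros(4), p=1)
        assert g.sse == pytest.approx(4.0)
        assert g.dfe == 3
        assert g.rmse == pytest.approx(math.sqrt(4.0 / 3.0), rel=1e-12)  # 1.1547

    def test_useless_parameter_lowers_adj_r2_only(self):
        obs = np.array([0.0, 1.0, 2.0, 2.5, 4.0, 5.2])
        fit = np.array([0.1, 0.9, 2.1, 2.6, 3.9, 5.1])
        g3, g4 = gof_metrics(obs, fit, p=3), gof_metrics(obs, fit, p=4)
        assert g3.r2 == g4.r2
        assert g4.adj_r2 < g3.adj_r2

    def test_constant_observations_rejected(self):
        with pytest.raises(DomainError):
            gof_metrics(np.ones(5), np.ones(5), p=1)


class TestSequentialBounds:
    def test_hand_computed_window(self):
        prev = MixtureFit(
            order=1,
            components=(GaussianComponent(1.0, 0.0, 10.0),),
            gof=None, n_restarts=1, seed=0,
        )
        (b,) = sequential_sigma_bounds(prev, dt=0.1, slopes=(0.491, 981.5), order=1)
        assert b[0] == pytest.approx(math.sqrt(100 + 0.0491), rel=1e-9)  # 10.0025
        assert b[1] == pytest.approx(math.sqrt(100 + 98.15), rel=1e-9)  # 14.077

    def test_first_profile_global_bounds(self):
        bounds = sequential_sigma_bounds(None, dt=0.5, slopes=(0.5, 900.0), order=3)
        assert bounds == [(1e-3, 100.0)] * 3

    def test_dt_zero_collapses(self):
        prev = MixtureFit(1, (GaussianComponent(1.0, 0.0, 7.0),), None, 1, 0)
        (b,) = sequential_sigma_bounds(prev, dt=0.0, slopes=(0.5, 900.0), order=1)
        assert b == (7.0, 7.0)

    def test_variance_never_shrinks(self):
        prev = MixtureFit(1, (GaussianComponent(1.0, 0.0, 12.0),), None, 1, 0)
        (b,) = sequential_sigma_bounds(prev, dt=0.3, slopes=(0.491, 981.5), order=1)
        assert b[0] >= 12.0

    def test_collapse_against_cap_raises(self):
        prev = MixtureFit(1, (GaussianComponent(1.0, 0.0, 100.0),), None, 1, 0)
        with pytest.raises(InfeasibleBoundsError):
            sequential_sigma_bounds(prev, dt=0.5, slopes=(10.0, 900.0), order=1)


class TestFitMixture:
    def test_single_gaussian_recovery(self, single_gaussian_profile):
        x, y = single_gaussian_profile
        fit = fit_mixture(x, y, 1, [(1e-3, 100.0)], seed=0)
        (comp,) = fit.components
        assert comp.amplitude == pytest.approx(100.0, rel=1e-6)
        assert comp.center == pytest.approx(0.0, abs=1e-6)
        assert comp.sigma == pytest.approx(10.0, rel=1e-6)
        assert fit.gof.rmse < 1e-8

    def test_two_component_recovery(self):
        x = np.arange(-150.0, 151.0)
        truth = [GaussianComponent(80.0, 0.0, 8.0), GaussianComponent(40.0, 0.0, 20.0)]
        y = mixture_value(truth, x)
        fit = fit_mixture(x, y, 2, [(1e-3, 100.0)] * 2, seed=1)
        wide, narrow = fit.components  # sigma-descending
        assert narrow.sigma == pytest.approx(8.0, rel=0.01)
        assert narrow.amplitude == pytest.approx(80.0, rel=0.01)
        assert wide.sigma == pytest.approx(20.0, rel=0.01)
        assert wide.amplitude == pytest.approx(40.0, rel=0.01)

    def test_bounds_respected(self):
        rng = np.random.default_rng(0)
        x = np.arange(-60.0, 61.0, 2.0)
        y = 50.0 * np.exp(-((x / 15.0) ** 2)) + rng.normal(0, 5.0, x.size)
        fit = fit_mixture(x, y, 2, [(5.0, 30.0), (2.0, 10.0)], seed=2)
        sig = sorted(c.sigma for c in fit.components)
        assert 2.0 <= sig[0] <= 10.0
        assert 5.0 <= sig[1] <= 30.0
        for c in fit.components:
            assert c.amplitude >= 0.0 and abs(c.center) <= 5.0

    def test_reproducible_given_seed(self, single_gaussian_profile):
        x, y = single_gaussian_profile
        f1 = fit_mixture(x, y, 1, [(1e-3, 100.0)], seed=42)
        f2 = fit_mixture(x, y, 1, [(1e-3, 100.0)], seed=42)
        assert f1 == f2

    def test_matches_grid_search_oracle(self):
        # <= 31-point profile with seeded noise; independent exhaustive search
        rng = np.random.default_rng(7)
        x = np.linspace(-15.0, 15.0, 31)
        y = 100.0 * np.exp(-(((x - 1.0) / 5.0) ** 2)) + rng.normal(0, 1.0, x.size)
        a_grid = np.linspace(80, 120, 41)  # step 1
        b_grid = np.linspace(-3, 3, 25)  # step 0.25
        c_grid = np.linspace(3, 8, 51)  # step 0.1
        (a, b, c), _ = grid_search_single_gaussian(x, y, a_grid, b_grid, c_grid)
        fit = fit_mixture(x, y, 1, [(1e-3, 100.0)], seed=3)
        comp = fit.components[0]
        assert abs(comp.amplitude - a) <= 1.0
        assert abs(comp.center - b) <= 0.25
        assert abs(comp.sigma - c) <= 0.1

    def test_nested_orders_never_worse(self):
        x = np.arange(-100.0, 101.0)
        y = mixture_value(
            [GaussianComponent(80.0, 0.0, 8.0), GaussianComponent(40.0, 0.0, 20.0)], x
        )
        sse = {}
        for order in (1, 2):
            fit = fit_mixture(x, y, order, [(1e-3, 100.0)] * order, seed=5)
            sse[order] = fit.gof.sse
        assert sse[2] <= sse[1] + 1e-9

    def test_too_few_points_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(DomainError):
            fit_mixture(x, np.ones(6), 2, [(1e-3, 100.0)] * 2, seed=0)

    def test_infeasible_bounds_rejected(self, single_gaussian_profile):
        x, y = single_gaussian_profile
        with pytest.raises(DomainError):
            fit_mixture(x, y, 1, [(10.0, 5.0)], seed=0)


class TestOrderScan:
    def test_pure_gaussian_order_one_suffices(self, single_gaussian_profile):
        x, y = single_gaussian_profile
        table = order_scan([("P00", x, y)], max_order=2, seed=0)
        assert set(table["order"]) == {1, 2}
        r2_order1 = table.loc[table["order"] == 1, "r2"].iloc[0]
        assert r2_order1 > 0.999

    def test_table_shape(self, single_gaussian_profile):
        x, y = single_gaussian_profile
        table = order_scan([("A", x, y), ("B", x, y)], max_order=3, seed=0)
        assert len(table) == 6
        assert {"sse", "rmse", "r2", "adj_r2", "point", "order"} <= set(table.columns)
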