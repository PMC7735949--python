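import itertools
import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_grid
from vbikit.behavior_space import GridSpec
from vbikit.kernel_regression import (
    KernelError,
    KernelSpec,
    fit_effect_maps,
    fit_pixel,
    kernel_weight,
    neighborhood,
    smoothed_predictor,
)


def enumerate_offsets(sigma):
    """Brute-force enumeration of integer offsets with a^2+b^2 <= (2s)^2."""
    r = math.ceil(2 * sigma)
    return [
        (a, b)
        for a, b in itertools.product(range(-r, r + 1), repeat=2)
        if a * a + b * b <= (2 * sigma) ** 2
    ]


class TestKernelWeight:
    def test_center_weight_is_one(self):
        assert kernel_weight((5, 5), (5, 5), 1.0) == 1.0

    def test_unit_distance(self):
        assert kernel_weight((5, 5), (5, 6), 1.0) == pytest.approx(math.exp(-0.5))

    def test_beyond_radius_is_outside(self):
        # d = 2.1 > 2 sigma for sigma = 1 (use a non-integer distance)
        assert kernel_weight((0, 0), (2, 1), 1.0) is None  # d = sqrt(5) > 2
        assert kernel_weight((0, 0), (2, 0), 1.0) is not None  # d = 2 = 2 sigma

    def test_invalid_sigma(self):
        with pytest.raises(KernelError):
            kernel_weight((0, 0), (0, 0), 0.0)


class TestNeighborhood:
    @pytest.mark.parametrize("sigma,expected_n", [(0.5, 5), (1.0, 13)])
    def test_interior_counts(self, sigma, expected_n):
        nb = neighborhood(20, 20, KernelSpec(sigma))
        assert len(nb.members) == expected_n
        assert len(nb.members) == len(enumerate_offsets(sigma))

    def test_interior_matches_enumeration(self):
        for sigma in (0.5, 1.0, 2.0):
            nb = neighborhood(20, 20, KernelSpec(sigma))
            got = {(a - 20, b - 20) for (a, b), _ in nb.members}
            assert got == set(enumerate_offsets(sigma))

    def test_corner_clipped_to_grid(self):
        nb = neighborhood(0, 0, KernelSpec(1.0))
        assert all(a >= 0 and b >= 0 for (a, b), _ in nb.members)
        interior = neighborhood(20, 20, KernelSpec(1.0))
        assert len(nb.members) < len(interior.members)

    def test_weights_decrease_with_distance(self):
        nb = neighborhood(10, 10, KernelSpec(2.0))
        for (a, b), w in nb.members:
            d2 = (a - 10) ** 2 + (b - 10) ** 2
            assert 0 < w <= 1
            assert w == pytest.approx(math.exp(-d2 / 8.0))
        ws = {(a - 10, b - 10): w for (a, b), w in nb.members}
        assert ws[(0, 0)] == 1.0
        assert ws[(0, 1)] > ws[(0, 2)] > ws[(0, 4)]

    def test_dihedral_symmetry_of_offsets(self):
        nb = neighborhood(20, 20, KernelSpec(1.5))
        offsets = {(a - 20, b - 20) for (a, b), _ in nb.members}
        for a, b in offsets:
            for sym in [(-a, b), (a, -b), (b, a), (-b, -a)]:
                assert sym in offsets


class TestSmoothedPredictor:
    def test_center_only_degenerate_kernel(self, rng, small_spec):
        grids = [random_grid(rng, small_spec, f"G{k}") for k in range(5)]
        nb = neighborhood(3, 3, KernelSpec(0.4), small_spec)  # radius 0.8 < 1
        assert len(nb.members) == 1
        x = smoothed_predictor(grids, nb)
        assert np.allclose(x, [g.grid[3, 3] for g in grids])

    def test_all_zero_grids(self, small_spec):
        from vbikit.behavior_space import PoTGrid

        grids = [
            PoTGrid(f"Z{k}", np.zeros((8, 8)), 0.0, small_spec) for k in range(4)
        ]
        nb = neighborhood(3, 3, KernelSpec(1.0), small_spec)
        assert np.all(smoothed_predictor(grids, nb) == 0)

    def test_matches_naive_double_loop(self, rng, small_spec):
        grids = [random_grid(rng, small_spec, f"G{k}") for k in range(7)]
        nb = neighborhood(4, 2, KernelSpec(1.0), small_spec)
        x = smoothed_predictor(grids, nb)
        for m, g in enumerate(grids):
            acc = 0.0
            for (a, b), w in nb.members:
                acc += w * g.grid[a, b]
            assert x[m] == pytest.approx(acc, abs=1e-12)


def ols_oracle(x, y):
    """Independent closed-form normal-equations fit with a t-test."""
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    beta = sxy / sxx
    intercept = ybar - beta * xbar
    resid = y - intercept - beta * x
    se = math.sqrt((resid**2).sum() / (n - 2) / sxx)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return beta, intercept, p


class TestFitPixel:
    def test_exact_collinearity(self):
        fit = fit_pixel(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        assert fit.beta == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.defined and fit.p_value < 1e-8

    def test_constant_predictor_undefined(self):
        fit = fit_pixel(np.ones(10), np.arange(10.0))
        assert not fit.defined

    def test_small_n_undefined(self):
        fit = fit_pixel(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert not fit.defined and fit.n_used == 2

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            fit = fit_pixel(x, y)
            beta, intercept, p = ols_oracle(x, y)
            assert abs(fit.beta - beta) < 1e-9
            assert abs(fit.intercept - intercept) < 1e-9
            assert abs(fit.p_value - p) < 1e-9

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        base = fit_pixel(x, y)
        scaled = fit_pixel(3.0 * x, y)
        assert scaled.beta == pytest.approx(base.beta / 3.0)
        assert scaled.p_value == pytest.approx(base.p_value, abs=1e-12)
        shifted = fit_pixel(x, y + 2.0)
        assert shifted.beta == pytest.approx(base.beta)
        assert shifted.intercept == pytest.approx(base.intercept + 2.0)


class TestFitEffectMaps:
    def _cohort(self, rng, n=20, spec=None):
        spec = spec or GridSpec(n_bins=8)
        grids = [random_grid(rng, spec, f"G{k}") for k in range(n)]
        sers = rng.normal(0, 1, n)
        return grids, sers

    def test_vectorised_fit_matches_pixelwise_route(self, rng, small_spec):
        grids, sers = self._cohort(rng, n=15, spec=small_spec)
        kernel = KernelSpec(1.0)
        maps = fit_effect_maps(grids, sers, kernel, alpha=0.05)
        for i, j in [(0, 0), (3, 4), (7, 7), (2, 6)]:
            nb = neighborhood(i, j, kernel, small_spec)
            x = smoothed_predictor(grids, nb)
            fit = fit_pixel(x, sers)
            assert maps.beta_map[i, j] == pytest.approx(fit.beta, abs=1e-10)
            assert maps.intercept_map[i, j] == pytest.approx(fit.intercept, abs=1e-10)
            assert maps.p_map[i, j] == pytest.approx(fit.p_value, abs=1e-10)

    def test_b_map_thresholding_exact(self, rng, small_spec):
        grids, sers = self._cohort(rng, n=25, spec=small_spec)
        maps = fit_effect_maps(grids, sers, KernelSpec(1.0), alpha=0.05)
        sig = maps.defined_map & (maps.p_map < 0.05)
        assert np.count_nonzero(maps.b_map) == sig.sum()
        assert np.all(maps.b_map[sig] == maps.beta_map[sig])
        assert np.all(maps.b_map[~sig] == 0)

    def test_tiny_alpha_gives_empty_b_map(self, rng, small_spec):
        grids, sers = self._cohort(rng, n=10, spec=small_spec)
        maps = fit_effect_maps(grids, sers, KernelSpec(1.0), alpha=1e-300)
        assert np.count_nonzero(maps.b_map) == 0

    def test_bh_correction_is_more_conservative(self, rng, small_spec):
        grids, sers = self._cohort(rng, n=30, spec=small_spec)
        raw = fit_effect_maps(grids, sers, KernelSpec(1.0), alpha=0.05)
        bh = fit_effect_maps(grids, sers, KernelSpec(1.0), alpha=0.05, correction="bh")
        assert np.count_nonzero(bh.b_map) <= np.count_nonzero(raw.b_map)

    def test_too_few_subjects_rejected(self, rng, small_spec):
        grids, sers = self._cohort(rng, n=2, spec=small_spec)
        with pytest.raises(KernelError):
            fit_effect_maps(grids, sers, KernelSpec(1.0))
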