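"""GWR kernels, bandwidth selection, and multiscale backfitting."""

import numpy as np
import pytest

from spathealth.exceptions import InvalidSpecError
from spathealth.mgwr import (KernelSpec, gwr_fit, kernel_weights, mgwr_fit,
                             report_scales, select_bandwidth, soc_f)
from spathealth.synthetic import (LatticeSpec, SurfaceScenario,
                                  gen_coefficient_surface, gen_covariates,
                                  gen_lattice, gen_outcome, make_multiscale_panel)


class TestKernel:
    def test_gaussian_closed_form(self):
        spec = KernelSpec(adaptive=False, bandwidth=2.0)
        w = kernel_weights(np.array([0.0, 2.0]), spec)
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(np.exp(-0.5))

    def test_adaptive_bandwidth_is_kth_order_statistic(self, rng):
        d = rng.uniform(0, 10, 10)
        d[0] = 0.0
        k = 4
        b = np.sort(d)[k - 1]  # exhaustive-sort oracle
        w = kernel_weights(d, KernelSpec(adaptive=True, bandwidth=k))
        np.testing.assert_allclose(w, np.exp(-0.5 * (d / b) ** 2))

    def test_monotone_decreasing_in_distance(self):
        d = np.linspace(0, 5, 50)
        w = kernel_weights(d, KernelSpec(adaptive=False, bandwidth=1.5))
        assert np.all(np.diff(w) < 0)

    def test_invalid_bandwidth_raises(self):
        with pytest.raises(InvalidSpecError):
            kernel_weights(np.array([1.0]), KernelSpec(adaptive=False, bandwidth=-1))


class TestGWR:
    def test_local_fit_matches_hand_solved_normal_equations(self, rng):
        """β at unit 0 from an explicitly accumulated 2×2 weighted system."""
        coords = rng.uniform(0, 5, (5, 2))
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        b = 2.5
        fit = gwr_fit(x, y, coords, KernelSpec(adaptive=False, bandwidth=b))
        d0 = np.linalg.norm(coords - coords[0], axis=1)
        w = np.exp(-0.5 * (d0 / b) ** 2)
        A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        rhs = np.array([(w * y).sum(), (w * x * y).sum()])
        np.testing.assert_allclose(fit.coefficients[0], np.linalg.solve(A, rhs), atol=1e-10)

    def test_fitted_plus_residual_is_y(self, rng):
        panel, coords, X, _ = make_multiscale_panel(side=8, noise_sd=0.5, seed=1)
        y = panel["life_expectancy"].to_numpy()
        fit = gwr_fit(X, y, coords, KernelSpec(bandwidth=20))
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-10)

    def test_noise_free_gradient_surface_recovered(self):
        lat = gen_lattice(LatticeSpec(16))
        coords = lat[["u", "v"]].to_numpy()
        X = gen_covariates(coords, 1, 0.0, seed=4)
        truth = gen_coefficient_surface(coords, SurfaceScenario("gradient", 2.0))
        surfaces = np.column_stack([np.ones(len(coords)), truth])
        y = gen_outcome(X, surfaces, noise_sd=0.0, seed=0)
        fit = gwr_fit(X, y, coords, KernelSpec(bandwidth=8))  # 8 of 256 neighbours
        r = np.corrcoef(fit.coefficients[:, 1], truth)[0, 1]
        assert r > 0.99


class TestBandwidthSelection:
    def test_golden_section_matches_exhaustive_grid(self):
        panel, coords, X, _ = make_multiscale_panel(side=10, noise_sd=0.5, seed=5)
        y = panel["life_expectancy"].to_numpy()
        chosen = select_bandwidth(X, y, coords)
        grid = {bw: gwr_fit(X, y, coords, KernelSpec(bandwidth=bw)).aicc
                for bw in range(6, 101)}
        best = min(grid, key=grid.get)
        assert abs(chosen - best) <= 1

    @pytest.mark.parametrize("seed", range(3))
    def test_global_process_selects_wider_bandwidth_than_local(self, seed):
        """The scale contrast AICc selection must resolve: a spatially
        constant process draws a far wider bandwidth than a hotspot process
        on the same lattice.  (With a Gaussian kernel the AICc profile for
        global data is nearly flat above moderate bandwidths, so the
        absolute selected value fluctuates; the contrast is the stable
        signature.)"""
        lat = gen_lattice(LatticeSpec(10))
        coords = lat[["u", "v"]].to_numpy()
        n = len(coords)
        X = gen_covariates(coords, 1, 0.0, seed=seed)
        y_global = gen_outcome(X, np.column_stack([np.full(n, 1.0), np.full(n, 2.0)]),
                               noise_sd=0.5, seed=seed)
        hot = gen_coefficient_surface(coords, SurfaceScenario("hotspot", 3.0, 2.5))
        y_local = gen_outcome(X, np.column_stack([np.ones(n), hot]),
                              noise_sd=0.3, seed=seed)
        bw_global = select_bandwidth(X, y_global, coords)
        bw_local = select_bandwidth(X, y_local, coords)
        assert bw_global > 2 * bw_local

    @pytest.mark.parametrize("seed", range(3))
    def test_local_process_selects_narrow_bandwidth(self, seed):
        lat = gen_lattice(LatticeSpec(12))
        coords = lat[["u", "v"]].to_numpy()
        n = len(coords)
        X = gen_covariates(coords, 1, 0.0, seed=seed)
        hot = gen_coefficient_surface(coords, SurfaceScenario("hotspot", 3.0, 3.0))
        y = gen_outcome(X, np.column_stack([np.ones(n), hot]), noise_sd=0.3, seed=seed)
        assert select_bandwidth(X, y, coords) < 0.2 * n


class TestSOC:
    def test_fixed_point_is_zero(self, rng):
        f = rng.standard_normal((10, 3))
        assert soc_f(f, f) == 0.0

    def test_hand_evaluation(self):
        f_new = np.array([[1.0, 2.0], [3.0, 4.0]])
        f_old = np.array([[1.5, 2.0], [3.0, 3.0]])
        # by hand: num = 0.25 + 1 = 1.25; denom = 2 * ((3)^2 + (7)^2) = 116
        assert soc_f(f_new, f_old) == pytest.approx(1.25 / 116.0, rel=1e-12)

    def test_joint_scaling_invariance(self, rng):
        f_new = rng.standard_normal((6, 2))
        f_old = f_new + rng.standard_normal((6, 2)) * 0.1
        assert soc_f(3.7 * f_new, 3.7 * f_old) == pytest.approx(soc_f(f_new, f_old), rel=1e-12)

    def test_all_zero_denominator_raises(self):
        with pytest.raises(InvalidSpecError):
            soc_f(np.zeros((4, 2)), np.ones((4, 2)))


class TestMGWR:
    def test_additive_decomposition_is_exact(self):
        panel, coords, X, _ = make_multiscale_panel(side=8, noise_sd=0.5, seed=2)
        y = panel["life_expectancy"].to_numpy()
        fit = mgwr_fit(X, y, coords, max_iterations=30, hat_matrix=False)
        ys = (y - y.mean()) / y.std()
        np.testing.assert_allclose(fit.terms.sum(axis=1) + fit.residuals, ys, atol=1e-10)

    def test_backfitting_equals_gwr_on_parametric_truth(self, rng):
        """With noise-free constant coefficients each term lies in its
        smoother's span, so the additive fixed point coincides with the
        joint GWR solution exactly."""
        panel, coords, X, _ = make_multiscale_panel(side=8, noise_sd=0.5, seed=3)
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        bw = 30
        g = gwr_fit(X, y, coords, KernelSpec(bandwidth=bw), add_intercept=True)
        m = mgwr_fit(X, y, coords, bandwidths=[bw] * 4, standardize=False,
                     tolerance=1e-14, max_iterations=500, hat_matrix=False)
        np.testing.assert_allclose(m.fitted, g.fitted, atol=1e-6)

    def test_global_truth_matches_ols_within_noise(self):
        from spathealth.regression import ols_fit
        lat = gen_lattice(LatticeSpec(10))
        coords = lat[["u", "v"]].to_numpy()
        n = len(coords)
        X = gen_covariates(coords, 2, 0.0, seed=9)
        surfaces = np.column_stack([np.full(n, 1.0), np.full(n, 2.0), np.full(n, -1.0)])
        noise_sd = 0.1
        y = gen_outcome(X, surfaces, noise_sd=noise_sd, seed=9)
        fit = mgwr_fit(X, y, coords, max_iterations=30, hat_matrix=False)
        assert np.all(fit.bandwidths >= 0.8 * n)
        ols = ols_fit(X, y)
        np.testing.assert_allclose(fit.fitted * y.std() + y.mean(), ols.fitted,
                                   atol=2 * noise_sd)

    def test_raw_coefficient_backtransform_roundtrip(self):
        panel, coords, X, _ = make_multiscale_panel(side=8, noise_sd=0.3, seed=6)
        y = panel["life_expectancy"].to_numpy()
        fit = mgwr_fit(X, y, coords, max_iterations=20, hat_matrix=False)
        raw = fit.raw_coefficients()
        design = np.column_stack([np.ones(len(y)), X])
        refit = np.sum(design * raw, axis=1)
        np.testing.assert_allclose(refit, fit.fitted * fit.y_sd + fit.y_mean, atol=1e-8)

    def test_enp_tracking_sums_to_plausible_trace(self):
        panel, coords, X, _ = make_multiscale_panel(side=7, noise_sd=0.5, seed=8)
        y = panel["life_expectancy"].to_numpy()
        fit = mgwr_fit(X, y, coords, max_iterations=40, hat_matrix=True)
        assert np.isfinite(fit.aicc)
        assert 0 < fit.enp.sum() < len(y)


class TestScales:
    def test_labels_and_boundaries(self):
        n = 2856
        assert report_scales([2857, 45], n) == ["global", "local"]
        assert report_scales([0.95 * n], n) == ["global"]     # boundary inclusive
        assert report_scales([0.95 * n - 1], n) == ["local"]
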