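"""Synthetic-data generators: determinism, contracts and oracles."""

import numpy as np
import pandas as pd
import pytest

from spathealth.exceptions import DimensionError, InvalidSpecError
from spathealth.inequality import AllocationTable, gini_direct, gini_trapezoid
from spathealth.lifetable import build_life_table
from spathealth.spatial import global_moran, lattice_rook_weights
from spathealth.synthetic import (AllocationSpec, LatticeSpec,
                                  MortalityScheduleSpec, SurfaceScenario,
                                  gen_allocation, gen_coefficient_surface,
                                  gen_covariates, gen_demography, gen_lattice,
                                  gen_outcome, gen_two_period_panel)


class TestLattice:
    def test_smallest_grid_coordinates(self):
        lat = gen_lattice(LatticeSpec(2, spacing=1.0))
        assert set(map(tuple, lat[["u", "v"]].to_numpy())) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_unit_count(self):
        assert len(gen_lattice(LatticeSpec(24))) == 576

    def test_determinism_and_uniqueness(self):
        a = gen_lattice(LatticeSpec(5, seed=3))
        b = gen_lattice(LatticeSpec(5, seed=3))
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(subset=["u", "v"]).any()

    def test_invalid_spec(self):
        with pytest.raises(InvalidSpecError):
            gen_lattice(LatticeSpec(1))
        with pytest.raises(InvalidSpecError):
            gen_lattice(LatticeSpec(3, spacing=0.0))


class TestSurfaces:
    def test_constant(self):
        coords = gen_lattice(LatticeSpec(3))[["u", "v"]].to_numpy()
        np.testing.assert_array_equal(
            gen_coefficient_surface(coords, SurfaceScenario("constant", 3.0)), 3.0)

    def test_hotspot_with_empty_support(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        s = gen_coefficient_surface(coords, SurfaceScenario("hotspot", 5.0, 1.0))
        np.testing.assert_array_equal(s, 0.0)

    def test_gradient_variance_matches_direct_evaluation(self):
        """Closed-form oracle: evaluate amplitude·(t−min)/(max−min) directly."""
        coords = gen_lattice(LatticeSpec(24))[["u", "v"]].to_numpy()
        s = gen_coefficient_surface(coords, SurfaceScenario("gradient", 2.0))
        t = coords.sum(axis=1)
        direct = 2.0 * (t - t.min()) / (t.max() - t.min())
        assert s.var() == pytest.approx(direct.var(), rel=1e-12)

    def test_unknown_kind_raises(self):
        with pytest.raises(InvalidSpecError):
            gen_coefficient_surface(np.zeros((2, 2)), SurfaceScenario("ridge", 1.0))


class TestCovariates:
    def test_standardization_contract(self):
        coords = gen_lattice(LatticeSpec(8))[["u", "v"]].to_numpy()
        X = gen_covariates(coords, 3, 0.4, seed=2)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-8)

    def test_iid_column_moran_near_null_expectation(self):
        side = 31
        coords = gen_lattice(LatticeSpec(side))[["u", "v"]].to_numpy()
        n = side * side
        X = gen_covariates(coords, 1, 0.0, seed=5)
        res = global_moran(X[:, 0], lattice_rook_weights(side), 999, seed=5)
        assert abs(res.z_score) < 3  # within 3 permutation SDs of −1/(n−1)

    def test_sar_smoothing_induces_positive_autocorrelation(self):
        side = 12
        coords = gen_lattice(LatticeSpec(side))[["u", "v"]].to_numpy()
        X = gen_covariates(coords, 1, 0.8, seed=6)
        res = global_moran(X[:, 0], lattice_rook_weights(side), 199, seed=6)
        assert res.I > 0.2

    def test_determinism_and_validation(self):
        coords = gen_lattice(LatticeSpec(4))[["u", "v"]].to_numpy()
        np.testing.assert_array_equal(gen_covariates(coords, 2, 0.3, seed=1),
                                      gen_covariates(coords, 2, 0.3, seed=1))
        with pytest.raises(InvalidSpecError):
            gen_covariates(coords, 2, 1.0, seed=1)


class TestOutcome:
    def test_noise_free_identity(self, rng):
        X = rng.standard_normal((20, 2))
        surfaces = np.column_stack([np.full(20, 1.0), np.full(20, 2.0), np.full(20, -3.0)])
        y = gen_outcome(X, surfaces, 0.0, seed=0)
        np.testing.assert_allclose(y, 1 + X @ [2.0, -3.0], atol=1e-12)

    def test_residual_sd_calibrated(self, rng):
        n = 576
        X = rng.standard_normal((n, 2))
        surfaces = np.ones((n, 3))
        y = gen_outcome(X, surfaces, 1.0, seed=3)
        eps = y - (1 + X.sum(axis=1))
        assert eps.std() == pytest.approx(1.0, rel=0.05)
        assert abs(eps.mean()) < 3 / np.sqrt(n)

    def test_shape_mismatch(self, rng):
        with pytest.raises(DimensionError):
            gen_outcome(rng.standard_normal((10, 2)), np.ones((10, 2)), 0.1)


class TestDemography:
    def test_deterministic_mode_supports_exact_q_recovery(self):
        """With expected deaths, the life table's interior q must equal the
        plug-in formula n·m/(1+(n/2)·m) at the generator's own hazards."""
        spec = MortalityScheduleSpec(seed=0)
        sched = gen_demography(spec)
        m = sched.deaths / sched.exposures
        lt = build_life_table(sched)
        widths = sched.widths[:-1]
        expected_q = widths * m[:-1] / (1 + widths / 2 * m[:-1])
        expected_q[0] = m[0]  # infant convention
        np.testing.assert_allclose(lt.q[:-1], expected_q, rtol=1e-12)

    def test_zero_infant_rate_gives_zero_infant_deaths(self):
        sched = gen_demography(MortalityScheduleSpec(infant_rate=0.0))
        assert sched.deaths[0] == 0.0

    def test_stochastic_mode_is_seeded_and_bounded(self):
        spec = MortalityScheduleSpec(seed=42)
        a = gen_demography(spec, stochastic=True)
        b = gen_demography(spec, stochastic=True)
        np.testing.assert_array_equal(a.deaths, b.deaths)
        assert np.all(a.deaths <= a.exposures)

    def test_invalid_edges(self):
        with pytest.raises(InvalidSpecError):
            gen_demography(MortalityScheduleSpec(interval_edges=()))
        with pytest.raises(InvalidSpecError):
            gen_demography(MortalityScheduleSpec(interval_edges=(5, 10)))


class TestAllocation:
    def test_sum_conservation(self, rng):
        pops = rng.uniform(100, 1e4, 30)
        for seed in range(5):
            Y = gen_allocation(pops, AllocationSpec(0.7, 500.0, seed))
            assert Y.sum() == pytest.approx(500.0, rel=1e-9)

    def test_high_concentration_limit_is_equal_per_capita(self, rng):
        pops = rng.uniform(100, 1e4, 40)
        Y = gen_allocation(pops, AllocationSpec(1e9, 100.0, 0))
        g = gini_direct(AllocationTable(pops, Y)).G
        assert g < 1e-3

    def test_low_concentration_gini_matches_trapezoid_oracle(self, rng):
        pops = rng.uniform(100, 1e4, 50)
        Y = gen_allocation(pops, AllocationSpec(0.1, 1.0, 7))
        t = AllocationTable(pops, Y)
        assert gini_direct(t).G == pytest.approx(gini_trapezoid(t), abs=1e-12)

    def test_gini_monotone_in_concentration(self, rng):
        pops = rng.uniform(100, 1e4, 60)
        ginis = []
        for conc in (0.05, 0.5, 5.0, 50.0, 5e3):
            gs = [gini_direct(AllocationTable(
                pops, gen_allocation(pops, AllocationSpec(conc, 1.0, s)))).G
                for s in range(10)]
            ginis.append(np.mean(gs))
        assert np.all(np.diff(ginis) <= 0)


class TestTwoPeriodPanel:
    def test_noise_free_ratio_follows_planted_form(self):
        df = gen_two_period_panel(70.0, (-0.1, 0.05), noise_sd=0.0, n=50, seed=1)
        np.testing.assert_allclose(df["beta2"] / df["beta1"], df["ratio_true"], atol=1e-12)

    def test_determinism(self):
        a = gen_two_period_panel(70.0, (-0.1, 0.05), 0.05, 100, seed=9)
        b = gen_two_period_panel(70.0, (-0.1, 0.05), 0.05, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nonfinite_slopes_rejected(self):
        with pytest.raises(InvalidSpecError):
            gen_two_period_panel(70.0, (np.inf, 0.1))
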