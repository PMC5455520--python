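"""Modulus extraction, load sharing, stress heterogeneity, fits."""

import numpy as np
import pandas as pd
import pytest

import rvenet as rv
from rvenet.coupling import LoadCase, ScaffoldModel, phase_reactions
from rvenet.matrix_fe import MatrixMaterial
from rvenet.postprocess import (
    InfeasibleTargetError,
    StressStrainSeries,
    equilibrium_modulus,
    fit_empirical_law,
    load_share_fractions,
    reverse_fit_mu,
    run_sweep,
    scaffold_modulus,
    stress_heterogeneity,
)


class TestEquilibriumModulus:
    def test_two_point_slope(self):
        E = equilibrium_modulus(StressStrainSeries([0.0, 0.05], [0.0, 5.0]))
        assert np.isclose(E, 100.0, rtol=1e-12)

    def test_midpoint_on_line_leaves_slope_unchanged(self):
        a = equilibrium_modulus(StressStrainSeries([0.0, 0.05], [0.0, 5.0]))
        b = equilibrium_modulus(StressStrainSeries([0.0, 0.025, 0.05], [0.0, 2.5, 5.0]))
        assert np.isclose(a, b, rtol=1e-12)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            equilibrium_modulus(StressStrainSeries([0.05], [5.0]))

    def test_strains_must_increase(self):
        with pytest.raises(ValueError):
            StressStrainSeries([0.05, 0.01], [1.0, 2.0])


class TestLoadShare:
    def test_reported_phase_loads_give_30_and_43_percent(self):
        m_lo, f_lo = load_share_fractions(270.9, 619.8)
        m_hi, f_hi = load_share_fractions(1124.0, 1474.0)
        assert round(m_lo) == 30 and round(m_hi) == 43
        assert np.isclose(m_lo + f_lo, 100.0) and np.isclose(m_hi + f_hi, 100.0)

    def test_pure_fiber_load(self):
        assert load_share_fractions(0.0, 42.0) == (0.0, 100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            load_share_fractions(0.0, 0.0)


class TestStressHeterogeneity:
    def test_pure_matrix_concentrates_at_affine_value(self):
        g = rv.RVEGeometry(10.0, 5)
        model = ScaffoldModel(g)
        sol = model.solve(11.0)
        hist = stress_heterogeneity(sol, MatrixMaterial(11.0))
        assert np.isclose(hist.masses.sum(), 1.0, atol=1e-12)
        # all elements share the homogeneous normalized stress ~ 3 * 0.05
        assert np.isclose(hist.sample_mean, 0.15, rtol=1e-3)
        assert hist.sample_variance < 1e-12
        lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
        assert lo <= hist.affine_value <= hi

    def test_histogram_masses_sum_to_one(self, tiny_model, tiny_solution):
        hist = stress_heterogeneity(tiny_solution, MatrixMaterial(11.0))
        assert np.isclose(hist.masses.sum(), 1.0, atol=1e-12)

    def test_stiffer_matrix_moves_distribution_toward_affine(self, tiny_model):
        sol_lo = tiny_model.solve(11.0)
        sol_hi = tiny_model.solve(50.0)
        h_lo = stress_heterogeneity(sol_lo, MatrixMaterial(11.0))
        h_hi = stress_heterogeneity(sol_hi, MatrixMaterial(50.0))
        assert h_hi.sample_variance < h_lo.sample_variance
        assert h_hi.mass_within(0.10) >= h_lo.mass_within(0.10)


@pytest.fixture(scope="module")
def matrix_only_model():
    return ScaffoldModel(rv.RVEGeometry(10.0, 5))


@pytest.fixture(scope="module")
def tiny_sweep():
    return run_sweep(
        [11.0, 50.0],
        [0.25, 0.5],
        replicates=2,
        geometry=rv.RVEGeometry(10.0, 5),
        base_seed=3,
    )


class TestReverseFit:
    @pytest.mark.parametrize("target,mu_expected", [(33.0, 11.0), (150.0, 50.0)])
    def test_recovers_closed_form_matrix_modulus(self, matrix_only_model, target, mu_expected):
        mu = reverse_fit_mu(target, matrix_only_model)
        assert abs(mu - mu_expected) / mu_expected < 0.02

    def test_unreachably_small_target_rejected(self, matrix_only_model):
        with pytest.raises(InfeasibleTargetError):
            reverse_fit_mu(0.05, matrix_only_model)

    def test_modulus_strictly_increasing_in_mu(self, tiny_model):
        Es = [scaffold_modulus(tiny_model, mu) for mu in (11.0, 30.0, 50.0)]
        assert Es[0] < Es[1] < Es[2]


class TestSweepAndFit:
    def test_single_cell_grid_matches_direct_solve(self):
        g = rv.RVEGeometry(10.0, 5)
        df = run_sweep([11.0], [0.25], replicates=1, geometry=g, base_seed=3)
        net = rv.network_for_concentration(g, 0.25, 3)
        beam = rv.discretize_fibers(net, 0.1)
        model = ScaffoldModel(g, beam)
        assert np.isclose(df["E_pa"].iloc[0], scaffold_modulus(model, 11.0), rtol=1e-9)

    def test_modulus_monotone_in_mu_and_concentration(self, tiny_sweep):
        by_mu = tiny_sweep.groupby(["cf_mg_ml", "mu_pa"])["E_pa"].mean()
        for cf in (0.25, 0.5):
            assert by_mu[cf][11.0] < by_mu[cf][50.0]
        by_cf = tiny_sweep.groupby(["mu_pa", "cf_mg_ml"])["E_pa"].mean()
        for mu in (11.0, 50.0):
            assert by_cf[mu][0.25] < by_cf[mu][0.5]

    def test_fiber_only_network_percolates(self, tiny_model):
        assert scaffold_modulus(tiny_model, 0.0) > 0

    def test_exact_linear_data_fit_recovered(self):
        mus = [10.0, 20.0, 30.0]
        cfs = [1.0, 2.0]
        rows = [
            {"mu_pa": m, "cf_mg_ml": c, "replicate": 0, "E_pa": 2 * m + 3 * c + 1}
            for m in mus
            for c in cfs
        ]
        fit = fit_empirical_law(pd.DataFrame(rows))
        assert np.isclose(fit.slope_mu, 2.0, atol=1e-9)
        assert np.isclose(fit.slope_cf, 3.0, atol=1e-9)
        assert np.isclose(fit.intercept, 1.0, atol=1e-8)
        assert np.isclose(fit.r_squared, 1.0, atol=1e-12)

    def test_noisy_linear_data_recovery_unbiased(self, rng):
        """Monte-Carlo: mean recovered coefficients within 2 SE of truth."""
        mus = np.array([11.0, 30.0, 50.0])
        cfs = np.array([1.0, 1.5, 3.0])
        grid = [(m, c) for m in mus for c in cfs]
        a, b, c0, sigma = 8.9, 105.0, -134.0, 20.0
        slopes_mu, slopes_cf = [], []
        for _ in range(100):
            rows = [
                {
                    "mu_pa": m,
                    "cf_mg_ml": c,
                    "replicate": 0,
                    "E_pa": a * m + b * c + c0 + sigma * rng.standard_normal(),
                }
                for m, c in grid
            ]
            fit = fit_empirical_law(pd.DataFrame(rows))
            slopes_mu.append(fit.slope_mu)
            slopes_cf.append(fit.slope_cf)
        se_mu = np.std(slopes_mu, ddof=1) / 10.0
        se_cf = np.std(slopes_cf, ddof=1) / 10.0
        assert abs(np.mean(slopes_mu) - a) < 2 * se_mu + 1e-9
        assert abs(np.mean(slopes_cf) - b) < 2 * se_cf + 1e-9

    def test_rank_deficient_design_rejected(self):
        rows = [
            {"mu_pa": m, "cf_mg_ml": 1.5, "replicate": 0, "E_pa": m}
            for m in (10.0, 20.0, 30.0, 40.0)
        ]
        with pytest.raises(ValueError):
            fit_empirical_law(pd.DataFrame(rows))

    def test_mu_cap_excludes_stiff_matrix_points(self):
        rows = [
            {"mu_pa": m, "cf_mg_ml": c, "replicate": 0, "E_pa": 2 * m + c}
            for m in (11.0, 50.0, 500.0)
            for c in (1.0, 3.0)
        ]
        fit = fit_empirical_law(pd.DataFrame(rows), mu_max=50.0)
        assert len(fit.grid) == 4
        assert (fit.grid["mu_pa"] <= 50.0).all()


def test_phase_fractions_from_tiny_solution(tiny_solution):
    f_m, f_f = phase_reactions(tiny_solution)
    m_pct, f_pct = load_share_fractions(f_m, f_f)
    assert 0 < m_pct < 100
    assert np.isclose(m_pct + f_pct, 100.0)
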