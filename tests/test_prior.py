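import numpy as np
import pandas as pd
import pytest

from permseq import (CovariateTrack, GenomeGrid, compute_position_priors,
                     fit_log_linear_prior, select_histone_covariates)
from permseq.covariates import AggregatedPriorTable
from permseq.prior import PriorModel, group_lasso_path, resolve_epsilon

from conftest import make_lasso_table, make_recovery_table


def single_knot_model(beta0=0.0, slope_total=0.0, lo=1.0, hi=5.0, **kw):
    """Degree-1 model with one linear segment: S(lo)=exp(beta0),
    S(hi)=exp(beta0+slope_total)."""
    return PriorModel(beta0=beta0, spline_coefs=np.array([slope_total]),
                      knots=np.array([lo, lo, hi, hi]), x_range=(lo, hi), **kw)


class TestFit:
    def test_constant_table_gives_flat_positive_curve(self):
        df = pd.DataFrame({"x_key": ["3", "5", "9"], "histone_pattern": "",
                           "S_bar": 5.0, "size": [4, 5, 6],
                           "x_rep": [3.0, 5.0, 9.0]})
        m = fit_log_linear_prior(AggregatedPriorTable(df, M=15))
        if len(m.spline_coefs):
            assert np.abs(m.spline_coefs).max() < 1e-6
        assert np.allclose(m.predict([3.0, 6.0, 9.0]), 5.0 + m.epsilon)

    def test_known_log_linear_curve_recovered(self):
        table = make_recovery_table(5)
        m = fit_log_linear_prior(table)
        x = np.arange(3, 201, dtype=float)
        true = np.exp(0.5 + 0.02 * x)
        assert np.max(np.abs(m.predict(x) - true) / true) < 0.05

    def test_monotone_data_give_monotone_fit(self):
        df = pd.DataFrame({"x_key": ["pooled_low", "3", "5"],
                           "histone_pattern": "", "S_bar": [1.0, 5.0, 10.0],
                           "size": [3, 2, 1], "x_rep": [1.0, 3.0, 5.0]})
        m = fit_log_linear_prior(AggregatedPriorTable(df, M=6))
        pred = m.predict([1.0, 3.0, 5.0])
        assert pred[0] < pred[1] < pred[2]

    def test_single_row_intercept_only(self):
        df = pd.DataFrame({"x_key": ["4"], "histone_pattern": "",
                           "S_bar": [2.0], "size": [10], "x_rep": [4.0]})
        m = fit_log_linear_prior(AggregatedPriorTable(df, M=10), epsilon=0.1)
        assert len(m.spline_coefs) == 0
        assert np.isclose(m.predict([4.0])[0], 2.1)

    def test_flat_extrapolation_beyond_range(self):
        m = fit_log_linear_prior(make_recovery_table(1))
        assert m.predict([500.0])[0] == m.predict([200.0])[0]
        assert m.predict([0.5])[0] == m.predict([3.0])[0]

    def test_predictions_always_positive(self):
        m = fit_log_linear_prior(make_lasso_table(0))
        x = np.linspace(0, 100, 57)
        codes = [np.zeros(57, int), np.full(57, 2)]
        assert m.predict(x, codes).min() > 0

    def test_empty_table_fatal(self):
        df = pd.DataFrame(columns=["x_key", "histone_pattern", "S_bar",
                                   "size", "x_rep"])
        with pytest.raises(ValueError):
            fit_log_linear_prior(AggregatedPriorTable(df, M=0))

    def test_auto_epsilon_caps_at_conventional_guard(self):
        assert resolve_epsilon(make_recovery_table(0), "auto") == 0.1
        df = pd.DataFrame({"x_key": ["3", "4"], "histone_pattern": "",
                           "S_bar": [0.05, 0.15], "size": [10, 10],
                           "x_rep": [3.0, 4.0]})
        small = resolve_epsilon(AggregatedPriorTable(df, M=20), "auto")
        assert np.isclose(small, 0.01)

    def test_serialization_round_trip(self, tmp_path):
        m = fit_log_linear_prior(make_lasso_table(2))
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = PriorModel.from_json(path)
        x = np.linspace(0, 80, 23)
        codes = [np.full(23, 1), np.full(23, 2)]
        assert np.allclose(m.predict(x, codes), m2.predict(x, codes))


class TestHistoneSelection:
    def test_unpenalized_limit_keeps_all(self):
        _, sets, _ = group_lasso_path(make_lasso_table(3), lambda_grid=[0.0])
        assert sets[0] == [0, 1]

    def test_full_shrinkage_drops_all(self):
        _, sets, _ = group_lasso_path(make_lasso_table(3), lambda_grid=[1e6])
        assert sets[0] == []

    def test_bic_keeps_informative_histone_only(self):
        m = select_histone_covariates(make_lasso_table(104))
        assert m.selected_histones == [1]
        # enriched rows carry roughly doubled counts
        base = m.predict([30.0], [np.array([0]), np.array([0])])[0]
        enr = m.predict([30.0], [np.array([0]), np.array([2])])[0]
        assert 1.5 < enr / base < 2.7

    def test_selection_path_is_nested(self):
        _, sets, _ = group_lasso_path(make_lasso_table(7), n_lambda=20)
        for a, b in zip(sets, sets[1:]):  # decreasing lambda
            assert set(a) <= set(b)

    def test_empty_grid_fatal(self):
        with pytest.raises(ValueError):
            select_histone_covariates(make_lasso_table(0), lambda_grid=[])


class TestPositionPriors:
    def test_flat_model_gives_unit_pseudocounts(self):
        grid = GenomeGrid(("chr1",), (10,))
        cov = CovariateTrack(grid, np.zeros(10, dtype=int))
        m = PriorModel(beta0=0.0, spline_coefs=np.zeros(0), knots=None,
                       x_range=(0.0, 0.0))
        pr = compute_position_priors(m, cov, grid)
        assert np.allclose(pr.values(np.arange(10)), 1.0)
        assert np.allclose(pr.gamma(np.arange(10)), 2.0)
        assert pr.total_mass == pytest.approx(10.0)

    def test_intercept_scales_total_mass(self):
        grid = GenomeGrid(("chr1",), (10,))
        cov = CovariateTrack(grid, np.zeros(10, dtype=int))
        m = PriorModel(beta0=np.log(3.0), spline_coefs=np.zeros(0), knots=None,
                       x_range=(0.0, 0.0))
        pr = compute_position_priors(m, cov, grid)
        assert pr.total_mass == pytest.approx(30.0)

    def test_total_mass_matches_hand_sum(self):
        # S(pooled low) = 1, S(5) = 4 on x = (0,...,0,5,5): total 8*1+2*4 = 16
        grid = GenomeGrid(("chr1",), (10,))
        x = np.array([0] * 8 + [5, 5])
        cov = CovariateTrack(grid, x)
        m = single_knot_model(beta0=0.0, slope_total=np.log(4.0), lo=1.0,
                              hi=5.0, low_rep=1.0)
        pr = compute_position_priors(m, cov, grid)
        assert np.allclose(pr.values(np.array([0, 8])), [1.0, 4.0])
        assert pr.total_mass == pytest.approx(16.0)

    def test_zero_coefficient_histone_changes_nothing(self):
        grid = GenomeGrid(("chr1",), (30,))
        rng = np.random.default_rng(0)
        x = rng.poisson(3.0, 30)
        plain = CovariateTrack(grid, x)
        with_h = CovariateTrack(grid, x, histone_codes=[
            rng.integers(0, 3, 30).astype(np.uint8)])
        m0 = single_knot_model(beta0=0.2, slope_total=0.5, lo=0.0, hi=10.0)
        m1 = single_knot_model(beta0=0.2, slope_total=0.5, lo=0.0, hi=10.0,
                               n_histones=1, selected_histones=[0],
                               histone_coefs=np.zeros((1, 2)))
        p0 = compute_position_priors(m0, plain, grid)
        p1 = compute_position_priors(m1, with_h, grid)
        idx = np.arange(30)
        assert np.allclose(p0.values(idx), p1.values(idx))
        assert p0.total_mass == pytest.approx(p1.total_mass)
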