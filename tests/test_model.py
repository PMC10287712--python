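"""Logit transform, OLS fitting, likelihood and the grid search contract."""

import numpy as np
import pandas as pd
import pytest

from chillqy import (
    CUConfig,
    GridSpec,
    assemble_design,
    compute_cu,
    fit_logit_linear,
    grid_search,
    inverse_logit,
    logit,
)
from _oracles import make_series, ols_ml_oracle


class TestLogit:
    def test_symmetry_point(self):
        assert logit(0.5) == 0.0

    def test_round_trip_identity(self):
        assert inverse_logit(logit(0.3)) == pytest.approx(0.3, abs=1e-12)

    def test_clamped_boundary_value(self):
        assert logit(0.0, eps=1e-3) == pytest.approx(np.log(0.001 / 0.999), abs=1e-12)
        assert logit(0.0, eps=1e-3) == pytest.approx(-6.9068, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            logit(1.2)

    def test_bad_eps_rejected(self):
        with pytest.raises(ValueError, match="eps"):
            logit(0.5, eps=0.7)


class TestAssembleDesign:
    @pytest.fixture
    def cu_and_obs(self):
        s = make_series(tavg=[2.0] * 10)
        cu = compute_cu(s, CUConfig("day_count", "avg", 5.0, 2))
        obs = pd.DataFrame(
            {
                "site_id": "s",
                "date": [s.dates[5]] * 3,
                "line": "line1",
                "replicate": [1, 2, 3],
                "qy": [0.4, 0.5, 0.6],
            }
        )
        return cu, obs

    def test_replicate_mean_before_logit(self, cu_and_obs):
        cu, obs = cu_and_obs
        design = assemble_design(cu, obs, "per_line_date_mean")
        assert len(design) == 1
        assert design["logit_qy"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_per_observation_keeps_every_leaf(self, cu_and_obs):
        cu, obs = cu_and_obs
        assert len(assemble_design(cu, obs, "per_observation")) == 3

    def test_empty_observations_rejected(self, cu_and_obs):
        cu, obs = cu_and_obs
        with pytest.raises(ValueError, match="empty"):
            assemble_design(cu, obs.iloc[:0])

    def test_uncovered_date_rejected(self, cu_and_obs):
        cu, obs = cu_and_obs
        obs.loc[0, "date"] = pd.Timestamp("1990-01-01")
        with pytest.raises(ValueError, match="1990-01-01"):
            assemble_design(cu, obs)


class TestFitLogitLinear:
    def test_exact_interpolation_of_collinear_pairs(self):
        x = np.array([0.0, 10, 20, 30, 40])
        y = -0.05 * x + 1
        fit = fit_logit_linear((x, y))
        assert fit.a == pytest.approx(-0.05, abs=1e-12)
        assert fit.b == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma**2 * fit.n_obs == pytest.approx(0.0, abs=1e-10)

    def test_aic_is_definitional_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0, 46, 20)
            y = -0.08 * x + 0.85 + rng.normal(0, 0.2, 20)
            fit = fit_logit_linear((x, y))
            assert fit.aic == 6.0 - 2.0 * fit.log_lik

    def test_log_likelihood_matches_density_oracle(self):
        x = np.array([0.0, 5.0, 12.0, 20.0, 33.0])
        y = np.array([0.9, 0.7, 0.4, -0.3, -1.5])
        fit = fit_logit_linear((x, y))
        a, b, sigma, log_lik, aic = ols_ml_oracle(x, y)
        assert fit.a == pytest.approx(a, rel=1e-12)
        assert fit.b == pytest.approx(b, rel=1e-12)
        assert fit.log_lik == pytest.approx(log_lik, abs=1e-9)
        assert fit.aic == pytest.approx(aic, abs=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logit_linear(([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_logit_linear(([1.0, 2.0], [0.1, 0.2]))

    def test_estimates_unbiased_over_replicates(self):
        rng = np.random.default_rng(42)
        a_true, b_true = -0.08, 0.85
        slopes, intercepts = [], []
        x = rng.uniform(0, 46, 30)
        for _ in range(500):
            y = a_true * x + b_true + rng.normal(0, 0.3, 30)
            fit = fit_logit_linear((x, y))
            slopes.append(fit.a)
            intercepts.append(fit.b)
        for est, true in [(slopes, a_true), (intercepts, b_true)]:
            err = np.mean(est) - true
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(err) < 3 * se

    def test_aic_invariant_to_predictor_shift(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 46, 25)
        y = -0.08 * x + 0.85 + rng.normal(0, 0.2, 25)
        f0 = fit_logit_linear((x, y))
        f1 = fit_logit_linear((x + 17.0, y))
        assert f1.aic == pytest.approx(f0.aic, abs=1e-8)

    def test_r_squared_within_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.uniform(0, 46, 15)
            y = rng.normal(0, 1, 15)
            fit = fit_logit_linear((x, y))
            assert 0.0 <= fit.r_squared <= 1.0


class TestGridSearch:
    def test_best_is_argmin_and_table_rectangular(self, home_data):
        series, obs = home_data
        spec = GridSpec.reduced([8.5, 9.0, 9.5, 10.0, 10.5], [42, 44, 46, 48, 50])
        result = grid_search(series, obs, spec)
        assert len(result.fits) == 6 * 5 * 5
        finite = result.fits["aic"]
        assert result.best.aic == finite.min()
        assert result.best.config in result.tie_report

    def test_failed_configs_carry_infinite_aic(self):
        # warm series: low thresholds give constant-zero CU -> failed rows
        s = make_series(tavg=np.linspace(18, 25, 120))
        dates = s.dates[80:110:5]
        obs = pd.DataFrame(
            {"site_id": "s", "date": np.repeat(dates, 2),
             "line": ["line1", "line2"] * len(dates),
             "replicate": 1,
             "qy": np.linspace(0.3, 0.7, 2 * len(dates))}
        )
        spec = GridSpec.reduced([-5.0, 21.0], [3, 7])
        result = grid_search(s, obs, spec)
        failed = result.fits[result.fits["failed"]]
        assert len(failed) > 0
        assert np.isinf(failed["aic"]).all()
        assert len(result.fits) == 6 * 2 * 2

    def test_all_failing_search_rejected(self):
        s = make_series(tavg=np.linspace(18, 25, 60))
        dates = s.dates[40:55:5]
        obs = pd.DataFrame(
            {"site_id": "s", "date": dates, "line": "line1", "replicate": 1,
             "qy": [0.3, 0.5, 0.7]}
        )
        spec = GridSpec.reduced([-20.0], [3])
        with pytest.raises(ValueError, match="all configurations failed"):
            grid_search(s, obs, spec)

    def test_insufficient_history_names_shortfall(self, home_data):
        series, obs = home_data
        short = type(series)("s", series.frame.loc[pd.Timestamp("2013-10-01"):])
        with pytest.raises(ValueError, match="history"):
            grid_search(short, obs, GridSpec.reduced([9.5], [70]))
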