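import numpy as np
import pandas as pd
import pytest

import chromahr as ch
from chromahr.regression import (
    DesignTable,
    adf_stationarity,
    fit_ar1,
    fit_poly_global,
    max_hr_percent,
    predict_ar1,
    summarize_cohort,
    vif_report,
)


def make_table(y, preds, names=("CR1", "CR2", "CR3"), age=25.0):
    return DesignTable(
        t=np.arange(len(y), dtype=float),
        y=np.asarray(y, dtype=float),
        predictors=pd.DataFrame(np.asarray(preds), columns=list(names)),
        participant_id="T",
        age=age,
    )


def simulate_ar1(n, a1=0.2, w1=0.9, wn=(0.5, 0.0, 0.0), noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    P = rng.uniform(0, 1, (n, 3))
    y = np.empty(n)
    y[0] = 2.0
    for t in range(1, n):
        y[t] = a1 + w1 * y[t - 1] + P[t - 1] @ np.asarray(wn) + rng.normal(0, noise_sd)
    return make_table(y, P)


class TestMaxHRPercent:
    def test_half_of_age_adjusted_max(self):
        assert max_hr_percent(110, 20) == pytest.approx(55.0)

    def test_reference_participant_value(self):
        assert max_hr_percent(191, 22) == pytest.approx(191 * 100 / 198)

    def test_identity_point(self):
        assert max_hr_percent(220 - 30, 30) == pytest.approx(100.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            max_hr_percent(100, 220)
        with pytest.raises(ValueError):
            max_hr_percent(0, 30)


class TestADF:
    def test_white_noise_is_stationary(self):
        rng = np.random.default_rng(1)
        res = adf_stationarity(rng.normal(size=500))
        assert res.stationary and res.p_value < 0.05

    def test_random_walk_is_not_stationary(self):
        rng = np.random.default_rng(2)
        res = adf_stationarity(np.cumsum(rng.normal(size=500)))
        assert not res.stationary

    def test_constant_series_degenerate_note(self):
        res = adf_stationarity(np.full(50, 3.0))
        assert res.stationary and "constant" in res.note

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            adf_stationarity(np.arange(5.0))


class TestFitAR1:
    def test_noiseless_recurrence_recovered_exactly(self):
        table = simulate_ar1(200, noise_sd=0.0)
        fit = fit_ar1(table)
        np.testing.assert_allclose(
            fit.params, [0.2, 0.9, 0.5, 0.0, 0.0], atol=1e-6
        )
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)
        assert len(fit.residuals) == len(table) - 1

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(12, 50))
            table = make_table(
                rng.uniform(1, 100, n), rng.uniform(0, 1, (n, 3))
            )
            fit = fit_ar1(table)
            X = np.column_stack(
                [np.ones(n - 1), table.y[:-1], table.predictors.to_numpy()[:-1]]
            )
            beta = np.linalg.solve(X.T @ X, X.T @ table.y[1:])
            np.testing.assert_allclose(fit.params, beta, atol=1e-8)

    def test_noisy_recovery_within_three_se(self):
        table = simulate_ar1(600, noise_sd=0.05, seed=3)
        fit = fit_ar1(table)
        truth = np.array([0.2, 0.9, 0.5, 0.0, 0.0])
        assert np.all(np.abs(fit.params - truth) < 3 * fit.se)

    def test_constant_predictor_named_in_rank_error(self):
        n = 50
        P = np.column_stack(
            [np.full(n, 0.5), np.linspace(0, 1, n), np.linspace(1, 0, n)]
        )
        table = make_table(np.linspace(10, 20, n), P)
        with pytest.raises(ValueError, match="CR1"):
            fit_ar1(table)


class TestPredictAR1:
    def test_self_prediction_consistency(self):
        table = simulate_ar1(300, noise_sd=0.05, seed=4)
        fit = fit_ar1(table)
        _, rmse = predict_ar1(fit, table)
        assert rmse == pytest.approx(fit.rmse)

    def test_noiseless_self_prediction_is_perfect(self):
        table = simulate_ar1(100, noise_sd=0.0)
        fit = fit_ar1(table)
        _, rmse = predict_ar1(fit, table)
        assert rmse == pytest.approx(0.0, abs=1e-8)

    def test_channel_name_mismatch_rejected(self):
        table = simulate_ar1(50)
        fit = fit_ar1(table)
        other = make_table(table.y, table.predictors.to_numpy(), names=("A", "B", "C"))
        with pytest.raises(ValueError, match="channel names"):
            predict_ar1(fit, other)

    def test_shuffled_predictors_do_not_beat_aligned_fit(self, rng):
        table = simulate_ar1(300, wn=(0.5, 0.3, -0.2), noise_sd=0.0, seed=5)
        base_rmse = fit_ar1(table).rmse
        for _ in range(20):
            perm = rng.permutation(len(table))
            shuffled = make_table(table.y, table.predictors.to_numpy()[perm])
            _, rmse = predict_ar1(fit_ar1(table), shuffled)
            assert rmse >= base_rmse


class TestPolyGlobal:
    def test_cubic_truth_fits_exactly(self, rng):
        P = rng.uniform(0, 1, (400, 3))
        y = 50 * P[:, 0] ** 3 + 10
        fit = fit_poly_global([make_table(y, P)], degree=3)
        assert fit.metrics.r_squared == pytest.approx(1.0, abs=1e-6)
        assert fit.metrics.rmse == pytest.approx(0.0, abs=1e-3)

    def test_underfitting_linear_model_has_larger_rmse(self, rng):
        P = rng.uniform(0, 1, (400, 3))
        y = 50 * P[:, 0] ** 3 + 10
        t = make_table(y, P)
        assert (
            fit_poly_global([t], degree=1).metrics.rmse
            > fit_poly_global([t], degree=3).metrics.rmse
        )

    def test_denominator_df_for_linear_three_predictor_pool(self, rng):
        # pooled n = 6064 with 3 linear terms -> df2 = 6064 - 3 - 1 = 6060
        P = rng.uniform(0, 1, (6064, 3))
        y = 40 + 20 * P[:, 0] + rng.normal(0, 1, 6064)
        fit = fit_poly_global([make_table(y, P)], degree=1)
        assert fit.metrics.df == (3, 6060)

    def test_insufficient_rows_rejected(self, rng):
        P = rng.uniform(0, 1, (10, 3))
        with pytest.raises(ValueError, match="insufficient"):
            fit_poly_global([make_table(np.linspace(1, 2, 10), P)], degree=3)

    def test_svr_estimator_runs(self, rng):
        P = rng.uniform(0, 1, (200, 3))
        y = 40 + 20 * P[:, 0]
        fit = fit_poly_global([make_table(y, P)], degree=2, estimator="svr")
        assert fit.metrics.rmse < 5.0


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        n = 64
        base = np.arange(n)
        X = np.column_stack(
            [np.sin(2 * np.pi * base / n), np.cos(2 * np.pi * base / n),
             np.sin(4 * np.pi * base / n)]
        )
        rep = vif_report(pd.DataFrame(X, columns=["a", "b", "c"]))
        for e in rep.entries:
            assert e.vif == pytest.approx(1.0, abs=1e-9)

    def test_exact_collinearity_flagged_infinite(self, rng):
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        with pytest.warns(UserWarning, match="collinear"):
            rep = vif_report(X)
        assert np.isinf(rep.entries[2].vif)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        z = rng.normal(size=200)
        X = np.column_stack(
            [0.7 * z + 0.3 * rng.normal(size=200) for _ in range(3)]
        )
        rep = vif_report(pd.DataFrame(X, columns=["u", "v", "w"]))
        Xc = sm.add_constant(X)
        for j, e in enumerate(rep.entries):
            assert e.vif == pytest.approx(
                variance_inflation_factor(Xc, j + 1), abs=1e-9
            )


class TestCohortSummary:
    def test_reference_cohort_matches_reported_summary(self):
        out = summarize_cohort(ch.REFERENCE_COHORT)
        assert out["age"]["mean"] == pytest.approx(26.89, abs=0.01)
        assert out["age"]["sd"] == pytest.approx(6.01, abs=0.01)
        assert out["weight"]["sd"] == pytest.approx(14.27, abs=0.01)

    def test_single_record_rejected_two_equal_give_zero_sd(self):
        with pytest.raises(ValueError):
            summarize_cohort([{"age": 20, "weight": 70, "height": 170}])
        out = summarize_cohort(
            [{"age": 20, "weight": 70, "height": 170}] * 2
        )
        assert out["age"]["sd"] == 0.0


class TestDesignTableValidation:
    def test_unnormalized_predictors_rejected(self):
        with pytest.raises(ValueError, match="min-max"):
            make_table(np.linspace(1, 2, 20), np.full((20, 3), 2.0))

    def test_missing_values_rejected(self):
        P = np.full((20, 3), 0.5)
        y = np.linspace(1, 2, 20)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            make_table(y, P)
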