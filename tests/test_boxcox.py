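"""Box-Cox regression: profile likelihood, prediction, screening."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm

from promkit import (
    ConfigurationError,
    DegenerateStatisticError,
    fit_boxcox,
    generate_cohort,
    predict_improvement,
    preset,
    screen_covariates,
)
from promkit.boxcox import BoxCoxModel, _design, _profile_loglik, predict_post

from conftest import boxcox_regression_cohort, make_cohort


class TestFit:
    def test_recovers_identity_transform_and_coefficients(self):
        cohort = boxcox_regression_cohort(1.0, 20_000, 31)
        model = fit_boxcox(cohort, degree=2)
        assert model.theta == pytest.approx(1.0, abs=0.1)
        # true generating coefficients (quadratic term absent)
        assert model.coefficients["const"] == pytest.approx(1.0, abs=0.1)
        assert model.coefficients["pre"] == pytest.approx(0.25, abs=0.02)
        assert model.coefficients["pre^2"] == pytest.approx(0.0, abs=5e-4)

    def test_recovers_square_root_transform(self):
        cohort = boxcox_regression_cohort(0.5, 20_000, 32)
        model = fit_boxcox(cohort, degree=2)
        assert model.theta == pytest.approx(0.5, abs=0.1)

    def test_theta_one_reproduces_ols(self):
        """At theta = 1 the transform is y - 1, so the fit must equal
        ordinary least squares on the raw response."""
        cohort = boxcox_regression_cohort(1.0, 2_000, 33)
        model = fit_boxcox(cohort, degree=2, theta_grid=(1.0, 1.0, 0.01))
        X, names = _design(cohort, 2, ())
        ols = sm.OLS(cohort.post, X).fit()  # z = (y-1)/1 = post + shift - 1
        for nm, b in zip(names, ols.params):
            assert model.coefficients[nm] == pytest.approx(b, abs=1e-6)

    def test_degree3_loglik_at_least_degree2(self, hip_ohs_50k):
        m2 = fit_boxcox(hip_ohs_50k, degree=2)
        m3 = fit_boxcox(hip_ohs_50k, degree=3)
        assert m3.loglik >= m2.loglik - 1e-6

    def test_profile_maximum_beats_dense_grid_oracle(self):
        cohort = boxcox_regression_cohort(0.5, 2_000, 34)
        model = fit_boxcox(cohort, degree=2)
        y = cohort.post + model.shift
        X, _ = _design(cohort, 2, ())
        q, _r = np.linalg.qr(X)
        sly = float(np.log(y).sum())
        dense = [
            _profile_loglik(t, y, q, sly) for t in np.arange(-2, 2.001, 0.002)
        ]
        assert model.loglik >= max(dense) - 1e-3

    def test_profile_is_unimodal_on_clean_data(self):
        cohort = boxcox_regression_cohort(0.5, 2_000, 35)
        y = cohort.post + 1.0
        X, _ = _design(cohort, 2, ())
        q, _r = np.linalg.qr(X)
        sly = float(np.log(y).sum())
        lls = np.array(
            [_profile_loglik(t, y, q, sly) for t in np.arange(-1.5, 1.6, 0.05)]
        )
        maxima = sum(
            1
            for i in range(1, len(lls) - 1)
            if lls[i] > lls[i - 1] and lls[i] >= lls[i + 1]
        )
        assert maxima == 1

    def test_constant_pre_score_is_rank_deficient(self):
        cohort = make_cohort([20.0] * 30, np.linspace(25, 45, 30))
        with pytest.raises(ConfigurationError, match="rank"):
            fit_boxcox(cohort, degree=2)

    def test_constant_response_rejected(self):
        cohort = make_cohort(np.linspace(5, 40, 30), [30.0] * 30)
        with pytest.raises(DegenerateStatisticError):
            fit_boxcox(cohort, degree=2)

    def test_json_round_trip(self, tmp_path):
        cohort = boxcox_regression_cohort(1.0, 500, 36)
        model = fit_boxcox(cohort, degree=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = BoxCoxModel.from_json(path)
        assert back == model


class TestPrediction:
    def _identity_model(self):
        return BoxCoxModel(
            theta=1.0,
            degree=2,
            shift=1.0,
            coefficients={"const": 5.0, "pre": 1.0, "pre^2": 0.0},
            sigma2=1.0,
            loglik=0.0,
            covariates_used=(),
            instrument="OHS",
            joint="hip",
            n=0,
        )

    def test_theta_one_prediction_is_the_fitted_line(self, small_cohort):
        model = self._identity_model()
        predicted = predict_post(model, small_cohort)
        np.testing.assert_allclose(predicted, 5.0 + small_cohort.pre)
        result = predict_improvement(model, small_cohort, threshold=5.0)
        # predicted change is exactly 5 for everyone -> all improved
        assert result.pct_total == 100.0

    def test_threshold_above_attainable_change_gives_zero(self, small_cohort):
        model = self._identity_model()
        result = predict_improvement(model, small_cohort, threshold=49.0)
        assert result.pct_total == 0.0

    def test_predicted_total_tracks_observed_on_calibrated_cohort(
        self, hip_ohs_50k
    ):
        """Internal consistency: the model's predicted improvement
        percentage lands within 5 points of the observed percentage."""
        model = fit_boxcox(hip_ohs_50k)
        result = predict_improvement(model, hip_ohs_50k, threshold=22)
        observed = 100 * np.mean(hip_ohs_50k.change >= 22)
        assert result.pct_total == pytest.approx(observed, abs=5.0)

    def test_undefined_predictions_counted_and_excluded(self, small_cohort):
        model = dataclasses.replace(
            self._identity_model(),
            theta=0.5,
            coefficients={"const": -10.0, "pre": 0.0, "pre^2": 0.0},
        )
        result = predict_improvement(model, small_cohort, threshold=5.0)
        assert result.n_undefined == len(small_cohort)
        assert result.pct_total is None

    def test_prediction_monotone_when_fitted_polynomial_monotone(self, hip_ohs_50k):
        model = fit_boxcox(hip_ohs_50k)
        pre = np.linspace(hip_ohs_50k.pre.min(), hip_ohs_50k.pre.max(), 200)
        c = model.coefficients
        slope = (
            c["pre"]
            + 2 * c["pre^2"] * pre
            + 3 * c.get("pre^3", 0.0) * pre**2
        )
        if (slope > 0).all() or (slope < 0).all():
            grid = make_cohort(pre, np.full_like(pre, 30.0))
            predicted = predict_post(model, grid)
            diffs = np.diff(predicted)
            assert (diffs >= -1e-9).all() or (diffs <= 1e-9).all()

    def test_mismatched_cohort_refused(self, hip_eq5d_50k):
        model = self._identity_model()
        with pytest.raises(ConfigurationError, match="fitted on"):
            predict_improvement(model, hip_eq5d_50k, threshold=22)

    def test_mean_prediction_exceeds_median_for_convex_inverse(self):
        cohort = boxcox_regression_cohort(0.5, 2_000, 37)
        model = fit_boxcox(cohort, degree=2)
        if model.theta < 1:  # inverse transform convex -> Jensen gap
            med = predict_post(model, cohort, method="median")
            mean = predict_post(model, cohort, method="mean")
            assert np.nanmean(mean - med) > 0


@pytest.fixture(scope="module")
def planted_cohort():
    spec = preset("hip-ohs", n=8_000, seed=2)
    spec = dataclasses.replace(
        spec,
        covariates=dataclasses.replace(
            spec.covariates, comorbidity_effects={"depression": -8.0}
        ),
    )
    return generate_cohort(spec)


class TestScreening:
    def test_planted_effect_selected_null_not(self, planted_cohort):
        report = screen_covariates(planted_cohort)
        assert "depression" in report.selected
        assert "liver_disease" not in report.selected
        assert "cancer" not in report.selected

    def test_vacuous_thresholds_select_everything(self, planted_cohort):
        report = screen_covariates(
            planted_cohort, chi2_threshold=0.0, coef_threshold=0.0
        )
        assert report.table["selected"].all()

    def test_null_covariates_never_selected_at_defaults(self):
        cohort = generate_cohort(preset("hip-ohs", n=5_000, seed=8))
        # preset effects are small relative to the screening cutoffs; a
        # covariate with no planted effect must never pass
        report = screen_covariates(cohort)
        table = report.table.set_index("candidate")
        for null in ("kidney", "liver_disease", "cancer", "stroke"):
            assert not table.loc[null, "selected"]
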