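"""INTime regression: published equation, screen, stepwise AICc, accuracy."""

import numpy as np
import pandas as pd
import pytest

from circaphase.core import ValidationError
from circaphase.intime import (PUBLISHED_COEFFS, PublishedINTime,
                               accuracy_summary, correlation_screen,
                               fit_intime, predict_bathyphase,
                               sample_size_stability)
from conftest import truth_frame


class TestPublishedEquation:
    def test_coefficients_are_printed_values(self):
        eq = PublishedINTime()
        assert eq.coefficients["sex"] == 1.33
        assert eq.coefficients["chronotype_score"] == -0.058
        assert eq.coefficients["center_of_rest"] == 0.472
        assert eq.coefficients["chest_bathyphase"] == -0.145

    def test_unit_sex_input(self):
        eq = PublishedINTime()
        zeros = {"sex": 1, "chronotype_score": 0, "center_of_rest": 0,
                 "chest_bathyphase": 0}
        assert eq.predict(zeros) == pytest.approx(1.33, abs=0)

    def test_all_zero_input(self):
        eq = PublishedINTime()
        assert eq.predict(dict.fromkeys(PUBLISHED_COEFFS, 0.0)) == 0.0

    def test_center_of_rest_slope(self):
        eq = PublishedINTime()
        base = {"sex": 0, "chronotype_score": 50, "center_of_rest": 27.0,
                "chest_bathyphase": 11.0}
        shifted = dict(base, center_of_rest=28.0)
        assert eq.predict(shifted) - eq.predict(base) == pytest.approx(0.472)

    def test_missing_covariate_named(self):
        with pytest.raises(ValidationError, match="chest_bathyphase"):
            PublishedINTime().predict({"sex": 1, "chronotype_score": 50,
                                       "center_of_rest": 27.0})

    def test_predict_bathyphase_published_no_band(self):
        point, band = predict_bathyphase(PublishedINTime(),
                                         {"sex": 1, "chronotype_score": 0,
                                          "center_of_rest": 0, "chest_bathyphase": 0})
        assert point == pytest.approx(1.33) and band is None


class TestCorrelationScreen:
    def test_self_correlation_and_antirank(self):
        n = 20
        df = pd.DataFrame({
            "center_of_rest": np.arange(n, dtype=float),
            "chronotype_score": np.arange(n, 0, -1, dtype=float),
            "sex": [0, 1] * (n // 2),
        })
        rep = correlation_screen(df, numeric_vars=["center_of_rest", "chronotype_score"])
        assert rep.spearman_r.loc["center_of_rest", "center_of_rest"] == 1.0
        assert rep.spearman_r.loc["center_of_rest", "chronotype_score"] == pytest.approx(-1.0)

    def test_recovers_generator_correlation(self):
        data = truth_frame(200, 51)
        rep = correlation_screen(data)
        r = rep.spearman_r.loc["chronotype_score", "center_of_rest"]
        assert r == pytest.approx(-0.7, abs=0.15)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            correlation_screen(pd.DataFrame({"center_of_rest": [1.0, 2.0]}))

    def test_sparse_cell_reported_missing(self):
        df = truth_frame(30, 52)
        df.loc[df.index[:28], "dlmo"] = np.nan
        rep = correlation_screen(df)
        assert np.isnan(rep.spearman_r.loc["dlmo", "center_of_rest"])


class TestFitINTime:
    def test_trace_strictly_improving(self):
        m = fit_intime(truth_frame(100, 61))
        scores = [s for _, _, s in m.selection_trace]
        assert all(b < a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_true_covariates_always_kept(self):
        m = fit_intime(truth_frame(200, 62))
        assert {"sex", "chronotype_score", "center_of_rest"} <= set(m.covariates)

    def test_pure_noise_covariates_mostly_rejected(self):
        rng = np.random.default_rng(0)
        empty = 0
        reps = 30
        for rep in range(reps):
            n = 100
            df = pd.DataFrame({
                "core_bathyphase": rng.normal(27.5, 1.0, n),
                "u1": rng.normal(size=n), "u2": rng.normal(size=n),
                "u3": rng.normal(size=n),
            })
            m = fit_intime(df, candidates=("u1", "u2", "u3"))
            empty += (m.covariates == [])
        assert empty / reps > 0.5

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            fit_intime(truth_frame(9, 63))

    def test_missing_dlmo_rows_restored_in_final_fit(self):
        data = truth_frame(120, 64)
        data.loc[data.index[:40], "dlmo"] = np.nan
        m = fit_intime(data)
        if "dlmo" not in m.covariates:
            assert m.nobs == 120  # refit on all rows complete for selected vars

    def test_coefficient_recovery_within_2se(self):
        """Refitting the generating covariate set recovers the published
        slopes within 2 standard errors in most replicates."""
        import statsmodels.api as sm
        reps = 40
        hits = {k: 0 for k in PUBLISHED_COEFFS}
        for rep in range(reps):
            data = truth_frame(200, 300 + rep)
            X = sm.add_constant(data[["sex", "chronotype_score",
                                      "center_of_rest", "chest_bathyphase"]])
            res = sm.OLS(data["core_bathyphase"], X).fit()
            for k in PUBLISHED_COEFFS:
                hits[k] += abs(res.params[k] - PUBLISHED_COEFFS[k]) <= 2 * res.bse[k]
        for k, h in hits.items():
            assert h / reps >= 0.9, f"{k}: {h}/{reps}"


class TestAccuracySummary:
    def test_identity(self):
        rep = accuracy_summary([27.0, 28.0], [27.0, 28.0],
                               bands=np.array([[26.5, 27.5], [27.5, 28.5]]))
        assert rep.median_error_h == 0.0
        assert rep.frac_within_1h == 1.0
        assert rep.band_coverage == 1.0

    def test_counting_example(self):
        errs_min = np.array([-30.0, 10.0, 50.0, 70.0]) / 60.0
        rep = accuracy_summary(27.0 + errs_min, np.full(4, 27.0))
        assert rep.frac_within_1h == pytest.approx(0.75)

    def test_wrap_safe_errors(self):
        rep = accuracy_summary([23.9], [24.1])
        assert rep.median_error_h == pytest.approx(-0.2)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            accuracy_summary([1.0], [1.0, 2.0])


class TestPredictionBands:
    def test_within_sample_coverage_near_nominal(self):
        data = truth_frame(300, 71)
        m = fit_intime(data, candidates=("sex", "chronotype_score",
                                         "center_of_rest", "chest_bathyphase"))
        rows = data.dropna(subset=["core_bathyphase", *m.covariates])
        pred, band = m.predict(rows, level=0.90)
        rep = accuracy_summary(pred, rows["core_bathyphase"], band)
        assert rep.band_coverage == pytest.approx(0.90, abs=0.05)

    def test_missing_covariate_error_names_it(self):
        m = fit_intime(truth_frame(100, 72),
                       candidates=("sex", "center_of_rest"))
        with pytest.raises(ValidationError, match="center_of_rest"):
            m.predict({"sex": 1})


class TestSampleSizeStability:
    @pytest.fixture(scope="class")
    def model(self):
        return fit_intime(truth_frame(33, 81),
                          candidates=("sex", "chronotype_score",
                                      "center_of_rest", "chest_bathyphase"))

    def test_width_decreases_with_n(self, model):
        res = sample_size_stability(model, [100, 400, 1600], trials=150, seed=5)
        w = res.widths[0.90].to_numpy()
        assert w[0] > w[1] > w[2]

    def test_zero_residuals_zero_width(self, model):
        import copy
        noiseless = copy.copy(model)
        noiseless.residuals = np.zeros_like(model.residuals)
        res = sample_size_stability(noiseless, [100, 200], trials=50, seed=1)
        assert (res.widths.to_numpy() == 0).all()

    def test_same_seed_identical(self, model):
        r1 = sample_size_stability(model, [100, 200], trials=60, seed=9)
        r2 = sample_size_stability(model, [100, 200], trials=60, seed=9)
        assert r1.widths.equals(r2.widths)
        assert r1.required_n == r2.required_n

    def test_grid_below_dimension_rejected(self, model):
        with pytest.raises(ValidationError):
            sample_size_stability(model, [4, 100], trials=10, seed=1)
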