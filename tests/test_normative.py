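"""GA trend fitting, the published normative model, z-scores and centiles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lungt2star import (
    CohortSpec,
    GATrendRegressor,
    NormativeModel,
    NormativeRegressor,
    fit_sd_trend,
    fit_trend,
    published_model,
    reference_band,
    simulate_cohort,
    simulate_designed_metric,
    zscore,
)


def cohort_frame(ga, values, subjects=None):
    subjects = subjects if subjects is not None else [f"s{i}" for i in range(len(ga))]
    return pd.DataFrame({"subject_id": subjects, "ga_weeks": ga, "v": values})


class TestFitTrend:
    def test_perfect_linearity_recovered_exactly(self):
        ga = np.linspace(21, 38, 30)
        fit = fit_trend(cohort_frame(ga, 3.5 + 1.25 * ga), "v")
        assert fit.slope == pytest.approx(1.25, abs=1e-10)
        assert fit.intercept == pytest.approx(3.5, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_metric_slope_ci_covers_zero(self):
        rng = np.random.default_rng(99)
        ga = rng.uniform(20.6, 38.3, 87)
        fit = fit_trend(cohort_frame(ga, rng.normal(50, 5, 87)), "v")
        half = 1.96 * fit.se_slope
        assert fit.slope - half < 0 < fit.slope + half

    def test_cluster_robust_changes_inference_not_estimates(self):
        rng = np.random.default_rng(5)
        n_sub = 40
        subj = np.repeat([f"s{i}" for i in range(n_sub)], 2)
        subj_effect = np.repeat(rng.normal(0, 5, n_sub), 2)
        ga = rng.uniform(21, 38, 2 * n_sub)
        v = 20 + 1.5 * ga + subj_effect + rng.normal(0, 1, 2 * n_sub)
        frame = cohort_frame(ga, v, subjects=subj)
        plain = fit_trend(frame, "v", cluster_by_subject=False)
        clustered = fit_trend(frame, "v", cluster_by_subject=True)
        assert clustered.slope == pytest.approx(plain.slope, abs=1e-12)
        assert clustered.intercept == pytest.approx(plain.intercept, abs=1e-12)
        assert clustered.se_slope != plain.se_slope
        assert clustered.n_subjects == n_sub and clustered.n_scans == 2 * n_sub

    def test_constant_ga_is_singular(self):
        with pytest.raises(ValueError, match="constant"):
            fit_trend(cohort_frame(np.full(10, 30.0), np.arange(10.0)), "v")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_trend(cohort_frame(np.array([21.0, 30.0]), np.array([1.0, 2.0])), "v")

    def test_slope_ci_covers_generating_slope_in_most_replicates(self):
        """Parameter recovery: >= 90% of 500 study-sized cohorts give a 95% CI
        containing the generating mean slope."""
        model = published_model()
        hits = 0
        for rep in range(500):
            table = simulate_cohort(CohortSpec(n_subjects=77), seed=10_000 + rep)
            reg = GATrendRegressor().fit(
                table[["ga_weeks"]], table["t2star_both_ms"]
            )
            lo, hi = reg.conf_int_slope_
            hits += lo <= model.mean_slope <= hi
        assert hits / 500 >= 0.90


class TestFitSdTrend:
    def test_homoskedastic_cohort_recovers_flat_sd(self):
        rng = np.random.default_rng(21)
        ga = rng.uniform(21, 38, 4000)
        frame = cohort_frame(ga, 10 + 2 * ga + rng.normal(0, 3.0, ga.size))
        sd_fit = fit_sd_trend(frame, "v", fit_trend(frame, "v"))
        assert sd_fit.sd_slope == pytest.approx(0.0, abs=0.05)
        assert sd_fit.sd_intercept == pytest.approx(3.0, rel=0.25)

    def test_zero_noise_cohort_gives_zero_sd_function(self):
        ga = np.linspace(21, 38, 50)
        frame = cohort_frame(ga, 10 + 2 * ga)
        sd_fit = fit_sd_trend(frame, "v", fit_trend(frame, "v"))
        assert sd_fit.sd_slope == pytest.approx(0.0, abs=1e-8)
        assert sd_fit.sd_intercept == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("method", ["residual", "binned"])
    def test_recovers_published_sd_coefficients_within_10pct(self, method):
        """Round trip: 200 draws per integer GA 21-38 from the published model."""
        ga = np.repeat(np.arange(21.0, 39.0), 200)
        table = simulate_designed_metric(ga, seed=12345)
        mean_fit = fit_trend(table, "t2star_both_ms")
        sd_fit = fit_sd_trend(table, "t2star_both_ms", mean_fit, method=method)
        model = published_model()
        assert sd_fit.sd_slope == pytest.approx(model.sd_slope, rel=0.10)
        assert sd_fit.sd_intercept == pytest.approx(model.sd_intercept, rel=0.10)

    def test_negative_fitted_sd_is_flagged(self):
        ga = np.linspace(21, 38, 600)
        rng = np.random.default_rng(8)
        noise_sd = np.clip(2.0 * (ga - 29.0), 0.01, None)  # ~zero noise low, large high
        frame = cohort_frame(ga, 10 + rng.normal(0, noise_sd))
        with pytest.warns(UserWarning, match="non-positive"):
            sd_fit = fit_sd_trend(frame, "v", fit_trend(frame, "v"))
        assert sd_fit.negative_sd_warning


class TestPublishedModel:
    def test_packaged_coefficients(self):
        m = published_model()
        assert m.mean_slope == 1.488884
        assert m.mean_intercept == 21.997645
        assert m.sd_slope == 1.488884
        assert m.sd_intercept == -18.451005
        assert m.ga_domain == (20.6, 38.3)

    def test_sd_positive_throughout_domain(self):
        m = published_model()
        assert m.sd(20.6) > 0  # 1.488884 * 20.6 - 18.451005 = 12.22 > 0
        assert m.sd(38.3) > 0

    def test_json_round_trip(self, tmp_path):
        m = published_model()
        m.to_json(tmp_path / "model.json")
        back = NormativeModel.from_json(tmp_path / "model.json")
        assert back == m


class TestZScores:
    def test_observation_on_mean_curve_is_z0_centile50(self):
        m = published_model()
        for ga in (21.0, 30.0, 38.0):
            res = zscore(float(m.mean(ga)), ga, m)
            assert res.z == pytest.approx(0.0, abs=1e-12)
            assert res.centile == pytest.approx(50.0)

    def test_one_sd_above_mean_is_z1(self):
        m = published_model()
        res = zscore(float(m.mean(25.0) + m.sd(25.0)), 25.0, m)
        assert res.z == pytest.approx(1.0)

    def test_two_sd_from_printed_formulas_is_z2(self):
        m = published_model()
        observed = (1.488884 * 30 + 21.997645) + 2 * (1.488884 * 30 - 18.451005)
        res = zscore(observed, 30.0, m)
        assert res.z == pytest.approx(2.0, abs=1e-12)
        assert res.centile == pytest.approx(97.725, abs=0.01)

    def test_out_of_domain_ga_names_valid_range(self):
        with pytest.raises(ValueError, match=r"20.6.*38.3"):
            zscore(60.0, 40.0, published_model())

    @given(q=st.floats(-4, 4), ga=st.floats(20.6, 38.3))
    def test_zscore_round_trip_identity(self, q, ga):
        m = published_model()
        res = zscore(float(m.mean(ga) + q * m.sd(ga)), ga, m)
        assert res.z == pytest.approx(q, abs=1e-9)


class TestReferenceBand:
    def test_median_centile_equals_mean_curve(self):
        m = published_model()
        band = reference_band(m, np.array([22.0, 30.0]), centiles=(50,))
        np.testing.assert_allclose(band.value, m.mean(band.ga_weeks))

    def test_symmetric_centiles_straddle_mean(self):
        m = published_model()
        band = reference_band(m, np.array([30.0]), centiles=(3, 97))
        lo, hi = band.value.to_numpy()
        assert lo + hi == pytest.approx(2 * float(m.mean(30.0)))

    def test_band_round_trips_through_zscore(self):
        m = published_model()
        for c in (3.0, 25.0, 50.0, 90.0):
            band = reference_band(m, np.array([27.5]), centiles=(c,))
            res = zscore(float(band.value.iloc[0]), 27.5, m)
            assert res.centile == pytest.approx(c, abs=1e-8)

    def test_monotone_in_centile_and_conditionally_in_ga(self):
        from scipy.stats import norm

        m = published_model()
        ga_grid = np.linspace(20.6, 38.3, 10)
        band = reference_band(m, ga_grid, centiles=(10, 50, 90))
        by_ga = band.pivot(index="ga_weeks", columns="centile", values="value")
        assert (by_ga.diff(axis=1).iloc[:, 1:] > 0).all().all()
        # increasing in GA exactly when mean_slope + z(c) * sd_slope > 0
        for c in (10.0, 50.0, 90.0):
            increasing = m.mean_slope + norm.ppf(c / 100.0) * m.sd_slope > 0
            diffs = by_ga[c].diff().iloc[1:]
            assert (diffs > 0).all() if increasing else (diffs < 0).all()

    def test_invalid_centiles_rejected(self):
        with pytest.raises(ValueError, match="centiles"):
            reference_band(published_model(), np.array([30.0]), centiles=(0.0, 50.0))


class TestNormativeRegressor:
    def test_full_model_recovery_from_designed_cohort(self):
        ga = np.repeat(np.arange(21.0, 39.0), 200)
        table = simulate_designed_metric(ga, seed=12345)
        reg = NormativeRegressor(metric="t2star_both_ms").fit(
            table[["ga_weeks"]], table["t2star_both_ms"]
        )
        m = reg.to_model()
        pub = published_model()
        assert m.mean_slope == pytest.approx(pub.mean_slope, rel=0.05)
        assert m.mean_intercept == pytest.approx(pub.mean_intercept, rel=0.05)
        assert m.sd_slope == pytest.approx(pub.sd_slope, rel=0.10)
        assert m.sd_intercept == pytest.approx(pub.sd_intercept, rel=0.10)

    def test_predict_is_fitted_mean_curve(self):
        ga = np.linspace(21, 38, 40)
        reg = NormativeRegressor().fit(ga, 5 + 2 * ga)
        np.testing.assert_allclose(reg.predict(np.array([25.0])), [55.0], atol=1e-8)
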