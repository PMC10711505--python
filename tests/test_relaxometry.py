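"""Mono-exponential decay fitting: exact recovery, clamping, robustness."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from lungt2star import (
    FitStatus,
    T2StarFitter,
    fit_loglinear,
    fit_map,
    fit_nlls,
    quality_mask,
    simulate_multiecho,
)

TE = np.array([13.8, 70.4, 127.0, 183.6, 240.2])
ALL_NONFAILED = (FitStatus.OK, FitStatus.CLAMPED_LOW, FitStatus.CLAMPED_HIGH)


def decay(s0, t2, te=TE):
    return s0 * np.exp(-te / t2)


class TestSingleVoxelFits:
    @pytest.mark.parametrize("fitter", [fit_loglinear, fit_nlls])
    @pytest.mark.parametrize("t2_true", [20.0, 66.0, 120.0, 200.0])
    def test_noiseless_exact_recovery(self, fitter, t2_true):
        res = fitter(decay(1000.0, t2_true), TE)
        assert res.status == FitStatus.OK
        assert res.t2star_ms == pytest.approx(t2_true, rel=1e-6)
        assert res.s0 == pytest.approx(1000.0, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_nlls_agrees_with_loglinear_on_noiseless_input(self):
        ll = fit_loglinear(decay(1000.0, 66.0), TE)
        nl = fit_nlls(decay(1000.0, 66.0), TE)
        assert nl.t2star_ms == pytest.approx(ll.t2star_ms, rel=1e-6)
        assert nl.s0 == pytest.approx(ll.s0, rel=1e-6)

    def test_constant_signal_clamps_high(self):
        res = fit_loglinear(np.full(5, 100.0), TE)
        assert res.status == FitStatus.CLAMPED_HIGH
        assert res.t2star_ms == 500.0

    def test_rising_signal_clamps_high(self):
        res = fit_loglinear(decay(1000.0, 66.0)[::-1], TE)
        assert res.status == FitStatus.CLAMPED_HIGH

    def test_very_fast_decay_clamps_low(self):
        res = fit_loglinear(decay(1000.0, 0.5, TE / 50), TE / 50)
        assert res.status == FitStatus.CLAMPED_LOW
        assert res.t2star_ms == 1.0

    def test_zero_sample_dropped_and_fit_succeeds(self):
        sig = decay(1000.0, 66.0)
        sig[-1] = 0.0
        res = fit_loglinear(sig, TE)
        assert res.status == FitStatus.OK
        assert res.t2star_ms == pytest.approx(66.0, rel=1e-6)

    @pytest.mark.parametrize("fitter", [fit_loglinear, fit_nlls])
    def test_fewer_than_three_positive_samples_fails_without_raising(self, fitter):
        sig = np.array([100.0, 50.0, 0.0, 0.0, 0.0])
        assert fitter(sig, TE).status == FitStatus.FAILED
        assert fitter(np.zeros(5), TE).status == FitStatus.FAILED

    @given(
        s0=st.floats(1.0, 1e5),
        t2=st.floats(5.0, 400.0),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_equivariance(self, s0, t2, c):
        """Scaling the signal by c scales fitted S0 by c and leaves T2* fixed."""
        base = fit_loglinear(decay(s0, t2), TE)
        scaled = fit_loglinear(c * decay(s0, t2), TE)
        assert scaled.t2star_ms == pytest.approx(base.t2star_ms, rel=1e-9)
        assert scaled.s0 == pytest.approx(c * base.s0, rel=1e-9)

    def test_te_units_consistency_seconds_vs_ms(self):
        """Fitting with TEs in seconds returns T2* in seconds (ms result / 1000)."""
        ms = fit_loglinear(decay(1000.0, 66.0), TE, t2_min=1.0, t2_max=500.0)
        sec = fit_loglinear(decay(1000.0, 66.0), TE / 1000.0, t2_min=1e-3, t2_max=0.5)
        assert sec.t2star_ms == pytest.approx(ms.t2star_ms / 1000.0, rel=1e-9)

    def test_nlls_less_biased_than_loglinear_under_rician_noise(self):
        """Monte-Carlo estimator comparison at SNR 20, truth 66 ms."""
        rng = np.random.default_rng(123)
        n = 2000
        sigma = 50.0  # S0 / SNR
        clean = decay(1000.0, 66.0)
        noisy = np.hypot(
            clean + rng.normal(0, sigma, (n, 5)), rng.normal(0, sigma, (n, 5))
        )
        t2_ll = np.array([fit_loglinear(s, TE).t2star_ms for s in noisy])
        t2_nl = np.array([fit_nlls(s, TE).t2star_ms for s in noisy])
        assert np.mean(np.abs(t2_nl - 66.0)) < np.mean(np.abs(t2_ll - 66.0))


class TestT2StarFitterEstimator:
    def test_transform_matches_single_voxel_fits(self):
        X = np.vstack([decay(1000.0, 66.0), decay(500.0, 120.0)])
        out = T2StarFitter(echo_times=TE, method="loglinear").fit(X).transform(X)
        assert out.shape == (2, 4)
        np.testing.assert_allclose(out[:, 1], [66.0, 120.0], rtol=1e-9)
        np.testing.assert_allclose(out[:, 0], [1000.0, 500.0], rtol=1e-9)

    def test_sklearn_params_round_trip(self):
        f = T2StarFitter(echo_times=TE, method="loglinear", t2_max=300.0)
        params = f.get_params()
        assert params["t2_max"] == 300.0
        f2 = T2StarFitter(echo_times=TE).set_params(**params)
        assert f2.get_params() == params

    def test_invalid_method_and_echo_times_rejected(self):
        with pytest.raises(ValueError, match="method"):
            T2StarFitter(echo_times=TE, method="magic").fit(np.ones((1, 5)))
        with pytest.raises(ValueError, match="echo_times"):
            T2StarFitter(echo_times=[1.0, 2.0]).fit(np.ones((1, 2)))


class TestFitMap:
    @pytest.mark.parametrize("method", ["loglinear", "nlls"])
    def test_noiseless_phantom_recovers_truth_map(self, phantom30, noiseless_image, method):
        body = phantom30.label_map > 0
        t2map = fit_map(noiseless_image, mask=body, method=method)
        rel = np.abs(t2map.t2star[body] - phantom30.truth_t2star[body]) / (
            phantom30.truth_t2star[body]
        )
        assert np.nanmax(rel) < 1e-6
        assert np.all(t2map.status[body] == FitStatus.OK)
        assert np.all(t2map.status[~body] == FitStatus.FAILED)

    def test_empty_mask_gives_all_failed_map(self, noiseless_image):
        t2map = fit_map(noiseless_image, mask=np.zeros(noiseless_image.shape, bool))
        assert np.all(t2map.status == FitStatus.FAILED)

    def test_grid_mismatch_rejected(self, noiseless_image):
        with pytest.raises(ValueError, match="grid"):
            fit_map(noiseless_image, mask=np.ones((2, 2, 2), bool))

    def test_noised_phantom_lung_median_within_5pct(self, phantom30):
        """At SNR 30 the Rician floor biases estimates but the lung median
        stays within 5% of the 66 ms truth."""
        from lungt2star import TissueParams, make_phantom

        tissues = [
            TissueParams(1, "right_lung", 1000.0, 66.0),
            TissueParams(2, "left_lung", 1000.0, 66.0),
            TissueParams(3, "body", 900.0, 40.0),
            TissueParams(4, "heart", 1100.0, 150.0),
        ]
        ph = make_phantom(29.56, (48,) * 3, tissues=tissues, seed=0)
        img = simulate_multiecho(ph, snr=30, noise_model="rician", seed=5)
        lungs = ph.lung_mask().labels > 0
        t2map = fit_map(img, mask=lungs, method="nlls")
        assert np.median(t2map.t2star[lungs]) == pytest.approx(66.0, rel=0.05)

    def test_nlls_never_worse_than_loglinear_in_sum_of_squares(self):
        rng = np.random.default_rng(4)
        clean = decay(1000.0, 66.0)
        noisy = np.hypot(clean + rng.normal(0, 80, (200, 5)), rng.normal(0, 80, (200, 5)))
        for sig in noisy:
            ll = fit_loglinear(sig, TE)
            nl = fit_nlls(sig, TE, init=ll)
            sse_ll = np.sum((sig - decay(ll.s0, ll.t2star_ms)) ** 2)
            sse_nl = np.sum((sig - decay(nl.s0, nl.t2star_ms)) ** 2)
            assert sse_nl <= sse_ll + 1e-9 * sse_ll


class TestQualityMask:
    def test_vacuous_threshold_keeps_all_nonfailed(self, phantom30, noiseless_image):
        t2map = fit_map(noiseless_image, mask=phantom30.label_map > 0, method="loglinear")
        qm = quality_mask(t2map, r2_min=0.0, statuses_allowed=ALL_NONFAILED)
        np.testing.assert_array_equal(qm, t2map.status != FitStatus.FAILED)

    def test_unsatisfiable_threshold_is_empty(self, phantom30, noiseless_image):
        t2map = fit_map(noiseless_image, mask=phantom30.label_map > 0, method="loglinear")
        assert not quality_mask(t2map, r2_min=1.0 + 1e-9).any()

    def test_noiseless_fit_is_perfect_everywhere_in_body(self, phantom30, noiseless_image):
        body = phantom30.label_map > 0
        t2map = fit_map(noiseless_image, mask=body, method="loglinear")
        qm = quality_mask(t2map, r2_min=0.99, statuses_allowed=ALL_NONFAILED)
        assert np.array_equal(qm, body)

    def test_negative_threshold_rejected(self, phantom30, noiseless_image):
        t2map = fit_map(noiseless_image, mask=phantom30.label_map > 0, method="loglinear")
        with pytest.raises(ValueError):
            quality_mask(t2map, r2_min=-0.1)
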