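"""Per-lag Gaussian fits, diffusion-law fitting, size and window analysis."""

import numpy as np
import pytest

from imsdkit.imsd import (
    IMSDCurve,
    build_imsd,
    fit_gaussian_lag,
    fit_imsd,
    size_from_intercept,
    window_analysis,
    window_lag_count,
)
from imsdkit.stics import CorrelationFunction, compute_correlation


def gaussian_slice(side=21, s2=4.0, A=1.0, y0=0.0):
    L = side // 2
    xx, yy = np.meshgrid(np.arange(-L, L + 1), np.arange(-L, L + 1))
    return A * np.exp(-(xx**2 + yy**2) / s2) + y0


class TestGaussianLagFit:
    def test_exact_gaussian_recovered(self):
        fit = fit_gaussian_lag(gaussian_slice(s2=4.0), pixel_size_nm=1000.0)
        assert fit.valid
        assert fit.sigma2_um2 == pytest.approx(4.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_pixel_size_conversion(self):
        fit = fit_gaussian_lag(gaussian_slice(s2=4.0), pixel_size_nm=69.0)
        assert fit.sigma2_um2 == pytest.approx(4.0 * 0.069**2, rel=1e-6)

    def test_noisy_gaussian_within_five_percent(self):
        errs = []
        for seed in range(100):
            g = gaussian_slice(s2=4.0) + np.random.default_rng(seed).normal(
                0.0, 0.01, (21, 21)
            )
            fit = fit_gaussian_lag(g, 1000.0)
            assert fit.valid
            errs.append(abs(fit.sigma2_um2 - 4.0) / 4.0)
        assert np.mean(errs) < 0.05

    def test_offset_recovered_and_zero_lag_excluded(self):
        g = gaussian_slice(s2=6.0, A=0.5, y0=0.2)
        g[10, 10] += 5.0  # shot-noise spike at zero lag must not matter
        fit = fit_gaussian_lag(g, 1000.0)
        assert fit.offset == pytest.approx(0.2, abs=1e-6)
        assert fit.sigma2_um2 == pytest.approx(6.0, abs=1e-6)

    def test_degenerate_slices_flagged_invalid(self):
        assert not fit_gaussian_lag(np.zeros((21, 21)), 69.0).valid
        assert not fit_gaussian_lag(np.full((21, 21), np.nan), 69.0).valid

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            fit_gaussian_lag(np.zeros((20, 20)), 69.0)


def synthetic_corr(tau, s2_um2, px_nm=69.0, max_lag=10, amplitude=1.0):
    """Noiseless correlation stack following a prescribed iMSD."""
    px_um2 = (px_nm / 1000.0) ** 2
    G = np.stack(
        [gaussian_slice(2 * max_lag + 1, s2 / px_um2, amplitude) for s2 in s2_um2]
    )
    return CorrelationFunction(
        G=G,
        tau=np.asarray(tau),
        max_lag=max_lag,
        n_pairs=np.full(len(tau), 100),
        pixel_size_nm=px_nm,
        frame_time_s=tau[0],
    )


class TestBuildIMSD:
    def test_recovers_prescribed_curve(self):
        tau = np.arange(1, 11) * 0.065
        s2 = 0.09 + 4 * 0.05 * tau
        curve = build_imsd(synthetic_corr(tau, s2))
        assert curve.n_valid == 10
        np.testing.assert_allclose(curve.sigma2, s2, rtol=1e-5)

    def test_too_few_valid_lags_rejected(self):
        tau = np.array([0.065, 0.13])
        with pytest.raises(ValueError, match="valid"):
            build_imsd(synthetic_corr(tau, np.array([0.05, 0.1])))

    def test_immobile_stack_gives_flat_curve(self, immobile_stack_small):
        stack, _, cfg = immobile_stack_small
        corr = compute_correlation(stack, 20, 10)
        curve = build_imsd(corr)
        fit = fit_imsd(curve, model="brownian")
        # growth over the window must be negligible vs the intercept
        growth = 4 * fit.D_M * curve.tau[-1]
        assert growth < 0.05 * fit.sigma0_sq

    def test_brownian_stack_slope_matches_D(self, brownian_stack_small):
        stack, _, cfg = brownian_stack_small
        corr = compute_correlation(stack, 20, 10)
        fit = fit_imsd(build_imsd(corr), model="brownian")
        assert fit.D_M == pytest.approx(cfg.D, rel=0.2)


class TestFitIMSD:
    def test_exact_model_inversion(self):
        tau = np.arange(1, 101) * 0.065
        s2 = 0.01 + 4 * 0.05 * tau
        curve = IMSDCurve(
            tau=tau, sigma2=s2, amplitude=np.ones_like(tau),
            offset=np.zeros_like(tau), r_squared=np.ones_like(tau),
            valid=np.ones_like(tau, bool),
        )
        for model in ("brownian", "anomalous"):
            fit = fit_imsd(curve, model=model)
            assert fit.D_M == pytest.approx(0.05, rel=1e-4)
            assert fit.alpha == pytest.approx(1.0, abs=1e-4)
            assert fit.sigma0_sq == pytest.approx(0.01, rel=1e-3)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-8)
        assert fit.size_nm == pytest.approx(100.0, rel=1e-3)

    def test_anomalous_exponent_recovered(self):
        tau = np.arange(1, 61) * 0.065
        for alpha in (0.6, 1.4):
            s2 = 0.04 + 4 * 0.02 * tau**alpha
            curve = IMSDCurve(
                tau=tau, sigma2=s2, amplitude=np.ones_like(tau),
                offset=np.zeros_like(tau), r_squared=np.ones_like(tau),
                valid=np.ones_like(tau, bool),
            )
            fit = fit_imsd(curve)
            assert fit.alpha == pytest.approx(alpha, abs=1e-3)
            assert fit.D_M == pytest.approx(0.02, rel=1e-2)

    def test_window_restricts_points(self):
        tau = np.arange(1, 101) * 0.065
        s2 = 0.01 + 0.2 * tau
        curve = IMSDCurve(
            tau=tau, sigma2=s2, amplitude=np.ones_like(tau),
            offset=np.zeros_like(tau), r_squared=np.ones_like(tau),
            valid=np.ones_like(tau, bool),
        )
        fit = fit_imsd(curve, window=(0.065, 10 * 0.065))
        assert fit.n_points == 10
        assert fit.tau_max == pytest.approx(0.65)

    def test_too_few_points_rejected(self):
        tau = np.arange(1, 101) * 0.065
        curve = IMSDCurve(
            tau=tau, sigma2=0.01 + 0.2 * tau, amplitude=np.ones_like(tau),
            offset=np.zeros_like(tau), r_squared=np.ones_like(tau),
            valid=np.ones_like(tau, bool),
        )
        with pytest.raises(ValueError, match="3"):
            fit_imsd(curve, window=(0.065, 0.13))


class TestSizeFromIntercept:
    def test_arithmetic(self):
        assert size_from_intercept(0.04) == pytest.approx(200.0)
        assert size_from_intercept(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            size_from_intercept(-0.01)

    def test_psf_correction_mode(self):
        assert size_from_intercept(0.05, psf_sigma0_sq_um2=0.01) == pytest.approx(200.0)


class TestWindowArithmetic:
    def test_lysosome_window_durations(self):
        # 460 frames at 65 ms: the 5/10/20% windows end at 1.5 / 3 / 6 s
        # (0.1 s rounding)
        for frac, expect_lags, expect_s in [(0.05, 23, 1.5), (0.10, 46, 3.0), (0.20, 92, 6.0)]:
            n = window_lag_count(460, frac)
            assert n == expect_lags
            assert round(n * 0.065, 1) == expect_s

    def test_boundary_fractions(self):
        assert window_lag_count(4, 1.0) == 4
        with pytest.raises(ValueError):
            window_lag_count(460, 0.001)
        with pytest.raises(ValueError):
            window_lag_count(460, 1.5)

    def test_window_analysis_produces_fingerprint(self, brownian_stack_small):
        stack, _, cfg = brownian_stack_small
        wa = window_analysis(stack, fractions=(0.10, 0.20), max_spatial_lag=12,
                             label="sim")
        assert len(wa.fits) == 2
        assert set(wa.fingerprint.columns) >= {"alpha", "size_nm", "D_M", "window_fraction"}
        assert (wa.fingerprint["acquisition"] == "sim").all()
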