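"""Windowed spectra, line fits, band selection and attenuation correction."""

import numpy as np
import pytest

from qustc.datatypes import ROIMask, RFFrame
from qustc.spectral import (
    DegenerateSpectrumWarning,
    SpectralConfig,
    SpectralFit,
    build_parametric_images,
    correct_attenuation,
    determine_band,
    fit_spectral_line,
    map_mask_to_windows,
    roi_statistics,
    windowed_power_spectrum,
)


class TestWindowedPowerSpectrum:
    def test_pure_tone_peak_bin(self):
        fs = 40e6
        t = np.arange(256) / fs
        seg = np.cos(2 * np.pi * 5e6 * t)
        freqs, power = windowed_power_spectrum(seg, fs)
        assert freqs[np.argmax(power)] == pytest.approx(5.0, abs=freqs[1])

    def test_all_zero_segment_floored_and_flagged(self):
        with pytest.warns(DegenerateSpectrumWarning):
            _, power = windowed_power_spectrum(np.zeros(64), 40e6, db_floor=-100.0)
        assert np.all(power == -100.0)

    def test_parseval(self, rng):
        seg = rng.standard_normal(128)
        freqs, power_db = windowed_power_spectrum(seg, 40e6)
        tapered = seg * np.hamming(len(seg))
        lin = 10.0 ** (power_db / 10.0)
        # rfft halves the spectrum: double all bins except DC and Nyquist
        weights = np.full(len(lin), 2.0)
        weights[0] = 1.0
        if len(seg) % 2 == 0:
            weights[-1] = 1.0
        assert np.sum(weights * lin) / len(seg) == pytest.approx(
            np.sum(tapered**2), rel=1e-10
        )

    def test_wrong_length_error(self):
        with pytest.raises(ValueError, match="length"):
            windowed_power_spectrum(np.zeros(64), 40e6, window_samples=125)


class TestFitSpectralLine:
    def test_flat_spectrum(self):
        f = np.linspace(0, 20, 81)
        fit = fit_spectral_line(f, np.full(81, -20.0), (4.0, 8.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-20.0)
        assert fit.midband == pytest.approx(-20.0)

    def test_exact_line_recovery(self):
        # P(f) = 10 - 2 f over [4, 8] MHz: s=-2, I=10, f0=6, M=-2
        f = np.linspace(0, 20, 81)
        fit = fit_spectral_line(f, 10.0 - 2.0 * f, (4.0, 8.0))
        assert fit.slope == pytest.approx(-2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(10.0, rel=1e-12)
        assert fit.band_center == pytest.approx(6.0)
        assert fit.midband == pytest.approx(-2.0, rel=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        f = np.linspace(2, 12, 41)
        for _ in range(50):
            p = 5.0 - 1.3 * f + rng.standard_normal(41)
            fit = fit_spectral_line(f, p, (3.0, 11.0))
            sel = (f >= 3.0) & (f <= 11.0)
            A = np.vstack([np.ones(sel.sum()), f[sel]]).T
            beta = np.linalg.solve(A.T @ A, A.T @ p[sel])
            assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
            assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_band_outside_grid_error(self):
        f = np.linspace(0, 10, 21)
        with pytest.raises(ValueError, match="outside"):
            fit_spectral_line(f, np.zeros(21), (8.0, 15.0))

    def test_midband_consistency_enforced(self):
        with pytest.raises(ValueError, match="midband"):
            SpectralFit(slope=1.0, intercept=0.0, midband=99.0, band_center=5.0)


class TestDetermineBand:
    def test_gaussian_minus6db_points(self):
        # Gaussian-shaped dB spectrum peaking at 7.5 MHz with -6 dB at 6/9 MHz
        f = np.arange(0, 20.25, 0.25)
        p = -6.0 * ((f - 7.5) / 1.5) ** 2
        band = determine_band(f, p, 6.0)
        assert band == (6.0, 9.0)

    def test_monotone_spectrum_clipped_with_flag(self):
        f = np.arange(0, 10.5, 0.5)
        with pytest.warns(DegenerateSpectrumWarning):
            band = determine_band(f, -f, 6.0)
        assert band[0] == 0.0

    def test_zero_drop_is_error(self):
        f = np.arange(0, 10.5, 0.5)
        p = -((f - 5.0) ** 2)
        with pytest.raises(ValueError, match="3 bins"):
            determine_band(f, p, 0.0)


class TestCorrectAttenuation:
    @pytest.mark.parametrize("alpha,depth", [(0.0, 3.0), (1.0, 0.0)])
    def test_identity_when_no_attenuation_term(self, alpha, depth):
        fit = SpectralFit(slope=-2.0, intercept=10.0, midband=-2.0,
                          band_center=6.0, depth_cm=depth)
        out = correct_attenuation(fit, alpha)
        assert out == fit

    def test_compensate_hand_value(self):
        # alpha=1 dB/MHz-cm, d=2 cm -> c=4: s' = -2+4 = 2, M' = 10+2*6 = 22
        fit = SpectralFit(slope=-2.0, intercept=10.0, midband=-2.0,
                          band_center=6.0, depth_cm=2.0)
        out = correct_attenuation(fit, 1.0, sign="compensate")
        assert out.slope == pytest.approx(2.0)
        assert out.midband == pytest.approx(22.0)
        assert out.intercept == fit.intercept

    def test_literal_sign_subtracts(self):
        fit = SpectralFit(slope=-2.0, intercept=10.0, midband=-2.0,
                          band_center=6.0, depth_cm=2.0)
        out = correct_attenuation(fit, 1.0, sign="subtract")
        assert out.slope == pytest.approx(-6.0)


class TestBuildParametricImages:
    def test_window_samples_and_positions(self, rng):
        # 2.4 mm at c/(2 fs)=19.25 um -> 125 samples; 1000-sample lines with
        # hop 16 -> 55 window positions
        frame = RFFrame(rng.standard_normal((1000, 4)), 40e6, 10e6)
        cfg = SpectralConfig()
        assert cfg.window_samples(frame) == 125
        with pytest.warns(DegenerateSpectrumWarning):
            ps = build_parametric_images(frame, cfg)
        assert ps.mbf_image.shape == (55, 4)
        assert np.all(np.diff(ps.window_centers) == 16)

    def test_frame_shorter_than_window_error(self, rng):
        frame = RFFrame(rng.standard_normal((100, 4)), 40e6, 10e6)
        with pytest.raises(ValueError, match="shorter"):
            build_parametric_images(frame, SpectralConfig())

    def test_midband_consistency_across_images(self, speckle_frame):
        frame, _, _ = speckle_frame
        ps = build_parametric_images(frame, SpectralConfig(attenuation_coefficient=0.0))
        f0 = ps.band_center
        np.testing.assert_allclose(
            ps.mbf_image, ps.int_image + ps.sl_image * f0, rtol=1e-10
        )

    def test_intercept_invariant_under_correction(self, speckle_frame):
        frame, _, _ = speckle_frame
        ps0 = build_parametric_images(frame, SpectralConfig(attenuation_coefficient=0.0))
        ps1 = build_parametric_images(frame, SpectralConfig(attenuation_coefficient=1.0))
        np.testing.assert_allclose(ps0.int_image, ps1.int_image)
        assert not np.allclose(ps0.sl_image, ps1.sl_image)

    def test_stationary_frame_slope_flat_with_depth(self, speckle_frame):
        # zero attenuation, stationary scattering: no depth trend in SL and
        # mean SL near the pulse-spectrum slope at band center (zero)
        import scipy.stats

        frame, _, _ = speckle_frame
        ps = build_parametric_images(frame, SpectralConfig(attenuation_coefficient=0.0))
        idx = np.arange(0, ps.sl_image.shape[0], 8)  # non-overlapping windows
        depth = ps.window_centers[idx] * frame.axial_spacing * 100.0
        sl = ps.sl_image[idx].mean(axis=1)
        res = scipy.stats.linregress(depth, sl)
        ci = scipy.stats.t.ppf(0.975, len(idx) - 2) * res.stderr
        assert abs(res.slope) < max(3 * ci, 0.15)
        assert abs(ps.sl_image.mean()) < 0.3


class TestROIStatistics:
    def test_constant_image(self):
        mask = ROIMask(np.ones((3, 3), dtype=bool))
        assert roi_statistics(np.full((3, 3), 7.0), mask) == (7.0, 0.0)

    def test_hand_value_n_minus_1(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[:] = True
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mean, sd = roi_statistics(img, ROIMask(mask))
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(1.2909944487358056)

    def test_single_pixel_sd_zero_flagged(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        with pytest.warns(DegenerateSpectrumWarning):
            mean, sd = roi_statistics(np.arange(9.0).reshape(3, 3), ROIMask(mask))
        assert (mean, sd) == (4.0, 0.0)


def test_mask_maps_to_window_grid():
    mask = np.zeros((100, 4), dtype=bool)
    mask[40:60] = True
    centers = np.array([10, 50, 90])
    out = map_mask_to_windows(mask, centers)
    np.testing.assert_array_equal(out, [[False] * 4, [True] * 4, [False] * 4])
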