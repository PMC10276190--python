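"""Tests for spectral-model fitting, sliding-window slopes and knee features."""

import numpy as np
import pytest

import eegslope as es
from eegslope.aperiodic import NoisePeaks


def power_law(freqs, b, chi):
    return 10.0**b * np.asarray(freqs, float) ** -chi


class TestFitLoglogLine:
    def test_exact_power_law(self):
        freqs = np.arange(40.0, 402.0, 2.0)
        b, chi = es.fit_loglog_line(freqs, power_law(freqs, 2.0, 1.5), (40, 400))
        assert b == pytest.approx(2.0, abs=1e-9)
        assert chi == pytest.approx(1.5, abs=1e-9)

    def test_spike_excluded_recovers_exactly(self):
        freqs = np.arange(20.0, 102.0, 2.0)
        power = power_law(freqs, 1.0, 2.0)
        power[freqs == 50.0] *= 100.0  # line-noise spike
        b, chi = es.fit_loglog_line(freqs, power, (20, 100), [(46, 54)])
        assert b == pytest.approx(1.0, abs=1e-9)
        assert chi == pytest.approx(2.0, abs=1e-9)

    def test_too_few_bins(self):
        freqs = np.array([10.0, 20.0, 30.0, 40.0])
        with pytest.raises(ValueError, match="3 usable bins"):
            es.fit_loglog_line(freqs, power_law(freqs, 0, 1), (10, 40), [(15, 45)])


class TestFitSpectralModel:
    def test_exact_power_law_recovery(self):
        freqs = np.arange(40.0, 402.0, 2.0)
        fit = es.fit_spectral_model(freqs, power_law(freqs, 2.0, 1.5), (40, 400))
        assert fit.offset == pytest.approx(2.0, abs=1e-3)
        assert fit.exponent == pytest.approx(1.5, abs=1e-3)
        assert fit.peaks == []
        assert fit.r_squared > 0.999

    def test_flat_spectrum_chi_zero(self):
        freqs = np.arange(4.0, 100.0, 2.0)
        fit = es.fit_spectral_model(freqs, np.ones_like(freqs), (4, 98))
        assert fit.exponent == pytest.approx(0.0, abs=1e-6)

    def test_peak_recovery(self):
        freqs = np.arange(4.0, 40.5, 0.5)
        params = es.SpectralModelParams(
            offset_b=1.0, exponent_chi=1.0, peaks=((0.6, 10.0, 2.0),)
        )
        power = es.evaluate_model_psd(params, freqs)
        fit = es.fit_spectral_model(
            freqs, power, (4, 40), es.FitSettings(peak_width_limits=(1, 8))
        )
        assert len(fit.peaks) >= 1
        tallest = max(fit.peaks)
        assert tallest[1] == pytest.approx(10.0, abs=0.5)
        assert fit.exponent == pytest.approx(1.0, abs=0.1)

    def test_agreement_with_line_fit_on_peak_free(self):
        freqs = np.arange(64.0, 142.0, 2.0)
        power = power_law(freqs, 1.3, 1.8)
        fit = es.fit_spectral_model(freqs, power, (64, 140))
        _, chi_line = es.fit_loglog_line(freqs, power, (64, 140))
        assert abs(fit.exponent - chi_line) < 0.01

    def test_scale_equivariance(self):
        freqs = np.arange(20.0, 200.0, 2.0)
        power = power_law(freqs, 1.0, 1.2)
        f1 = es.fit_spectral_model(freqs, power, (20, 198))
        f2 = es.fit_spectral_model(freqs, 100.0 * power, (20, 198))
        assert f2.offset - f1.offset == pytest.approx(2.0, abs=1e-6)
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-9)

    def test_grid_invariance(self):
        coarse = np.arange(40.0, 400.0, 2.0)
        fine = np.arange(40.0, 400.0, 0.5)
        chi_c = es.fit_spectral_model(coarse, power_law(coarse, 1, 1.5), (40, 398)).exponent
        chi_f = es.fit_spectral_model(fine, power_law(fine, 1, 1.5), (40, 398)).exponent
        assert abs(chi_c - chi_f) < 1e-3

    def test_negative_exponent_allowed(self):
        freqs = np.arange(56.0, 86.0, 2.0)
        fit = es.fit_spectral_model(freqs, power_law(freqs, 0.0, -0.5), (56, 84))
        assert fit.exponent == pytest.approx(-0.5, abs=1e-3)

    def test_too_few_bins_reports_failure(self):
        freqs = np.array([10.0, 12.0, 14.0])
        fit = es.fit_spectral_model(freqs, np.ones(3), (10, 14))
        assert fit.failed

    def test_default_settings_match_conditions(self):
        assert es.FitSettings.for_condition("eyes_open").peak_width_limits == (4, 8)
        assert es.FitSettings.for_condition("eyes_closed").peak_width_limits == (1, 8)
        s = es.FitSettings()
        assert s.max_n_peaks == 5
        assert s.min_peak_height == 0.2
        assert s.peak_threshold == 2.0
        assert s.aperiodic_mode == "fixed"


class TestMakeWindows:
    def test_default_grid_has_47_windows(self):
        windows = es.make_windows()
        assert len(windows) == 47  # (960 - 40)/20 + 1

    def test_first_window_clipped(self):
        centre, (lo, hi) = es.make_windows()[0]
        assert centre == 40 and (lo, hi) == (4, 90)

    def test_last_window(self):
        centre, (lo, hi) = es.make_windows()[-1]
        assert centre == 960 and (lo, hi) == (910, 1000)

    def test_step_greater_than_width_rejected(self):
        with pytest.raises(ValueError, match="step"):
            es.make_windows(step=200, width=100)


class TestNoisePeaks:
    def test_bands_are_50k_plus_minus_4(self):
        np_bands = NoisePeaks().bands
        assert np_bands[0] == (46, 54)
        assert np_bands[1] == (96, 104)
        assert all(hi - lo == 8 for lo, hi in np_bands)

    def test_hfr_endpoints_never_in_band(self):
        noise = NoisePeaks()
        assert not noise.contains(230.0)
        assert not noise.contains(430.0)


class TestSlidingSlopes:
    FREQS = np.arange(4.0, 1002.0, 2.0)

    def test_window_50_150_excluded(self):
        power = power_law(self.FREQS, 2.0, 1.5)
        prof = es.sliding_slopes(self.FREQS, power, method="line")
        i = np.where(prof.centre_freqs == 100.0)[0][0]
        assert np.isnan(prof.exponents[i])
        assert prof.reasons[i] == "noise_peak_at_edge"

    def test_interior_noise_bins_removed(self):
        # window [110, 210]: endpoints clear; 150 and 200 Hz interior spikes
        power = power_law(self.FREQS, 2.0, 2.0)
        for f0 in (150.0, 200.0):
            power[self.FREQS == f0] *= 50.0
        prof = es.sliding_slopes(self.FREQS, power, method="line")
        i = np.where(prof.centre_freqs == 160.0)[0][0]
        assert prof.window_ranges[i] == (110.0, 210.0)
        assert prof.exponents[i] == pytest.approx(2.0, abs=1e-6)

    def test_small_slope_marked_missing(self):
        power = power_law(self.FREQS, 0.0, 0.005)
        prof = es.sliding_slopes(self.FREQS, power, method="line")
        usable = ~np.isnan(prof.exponents)
        assert not usable.any()
        reasons = {r for r in prof.reasons if r is not None}
        assert reasons <= {"below_min_slope", "noise_peak_at_edge"}
        assert "below_min_slope" in reasons

    def test_power_law_recovered_everywhere_usable(self):
        power = power_law(self.FREQS, 2.0, 1.5)
        prof = es.sliding_slopes(self.FREQS, power, method="line")
        ok = ~np.isnan(prof.exponents)
        assert ok.sum() > 30
        np.testing.assert_allclose(prof.exponents[ok], 1.5, atol=1e-6)

    def test_uncovered_windows_no_data(self):
        freqs = np.arange(4.0, 402.0, 2.0)
        prof = es.sliding_slopes(freqs, power_law(freqs, 1, 1), method="line")
        high = prof.centre_freqs > 460
        assert all(r == "no_data" for r, h in zip(prof.reasons, high) if h)


class TestBandSlope:
    FREQS = np.arange(4.0, 1002.0, 2.0)

    def test_lfr_hfr_on_single_power_law(self):
        power = power_law(self.FREQS, 1.0, 1.0)
        lfr, _ = es.band_slope(self.FREQS, power, "LFR", method="line")
        hfr, _ = es.band_slope(self.FREQS, power, "HFR", method="line")
        assert lfr == pytest.approx(1.0, abs=1e-6)
        assert hfr == pytest.approx(1.0, abs=1e-6)

    def test_two_regime_generator_recovery(self):
        params = es.SpectralModelParams(
            offset_b=2.0, exponent_chi=1.0, knee_freq=175.0, exponent_hi=2.0
        )
        power = es.evaluate_model_psd(params, self.FREQS)
        lfr, _ = es.band_slope(self.FREQS, power, "LFR", method="line")
        hfr, _ = es.band_slope(self.FREQS, power, "HFR", method="line")
        assert lfr == pytest.approx(1.0, abs=0.1)
        assert hfr == pytest.approx(2.0, abs=0.1)

    def test_below_min_slope_missing(self):
        power = power_law(self.FREQS, 0.0, 0.005)
        chi, reason = es.band_slope(self.FREQS, power, "LFR", method="line")
        assert np.isnan(chi)
        assert reason == "below_min_slope"


class TestAlphaPeak:
    def _fit_with_peaks(self, peaks):
        return es.AperiodicFit(1.0, 1.0, peaks, (4.0, 40.0), 0.99)

    def test_single_peak_at_10(self):
        assert es.extract_alpha_peak(self._fit_with_peaks([(0.5, 10.0, 2.0)])) == 10.0

    def test_no_peak_in_band(self):
        assert es.extract_alpha_peak(self._fit_with_peaks([(0.5, 20.0, 2.0)])) is None

    def test_tallest_in_band_wins(self):
        fit = self._fit_with_peaks([(0.3, 9.0, 1.0), (0.8, 11.0, 1.0), (1.5, 25.0, 2.0)])
        assert es.extract_alpha_peak(fit) == 11.0

    def test_generator_alpha_recovered(self):
        freqs = np.arange(4.0, 40.5, 0.5)
        params = es.SpectralModelParams(
            offset_b=1.5, exponent_chi=1.0, peaks=((0.8, 9.5, 1.2),)
        )
        power = es.evaluate_model_psd(params, freqs)
        fit = es.fit_spectral_model(
            freqs, power, (4, 40), es.FitSettings(peak_width_limits=(1, 8))
        )
        assert es.extract_alpha_peak(fit) == pytest.approx(9.5, abs=0.5)


class TestKnee:
    def _profile(self, centres, exponents):
        return es.SlopeProfile(
            centre_freqs=np.array(centres, float),
            exponents=np.array(exponents, float),
            window_ranges=[(c - 50, c + 50) for c in centres],
            reasons=[None] * len(centres),
        )

    def test_unique_minimum(self):
        prof = self._profile([140, 160, 180, 200, 220], [1.0, 0.8, 0.5, 0.9, 1.2])
        res = es.find_knee(prof)
        assert res.f_knee == 180.0
        assert not res.at_boundary

    def test_monotone_profile_boundary_flag(self):
        prof = self._profile([120, 160, 200, 240], [0.5, 0.8, 1.1, 1.4])
        res = es.find_knee(prof)
        assert res.f_knee == 120.0
        assert res.at_boundary

    def test_tie_takes_lowest_frequency(self):
        prof = self._profile([120, 160, 200, 240], [1.0, 0.5, 0.5, 1.0])
        assert es.find_knee(prof).f_knee == 160.0

    def test_too_few_points(self):
        prof = self._profile([120, 160], [1.0, 0.5])
        assert es.find_knee(prof) is None

    def test_realized_knee_matches_analytic_oracle(self):
        """Synthetic slope dip near 175 Hz: pipeline knee vs analytic-PSD oracle."""
        params = es.SpectralModelParams(
            offset_b=2.5,
            exponent_chi=2.5,
            emg_band=(180 / np.sqrt(10), 180 * np.sqrt(10), 180.0, 0.004),
        )
        freqs = np.arange(4.0, 1002.0, 2.0)
        oracle_prof = es.sliding_slopes(
            freqs, es.evaluate_model_psd(params, freqs), method="line"
        )
        oracle = es.find_knee(oracle_prof).f_knee

        x = es.synthesize_timeseries(params, 30.0, 2500.0, seed=6)[0]
        epochs = es.EpochSet(
            epochs=x[: 60 * 1250].reshape(1, 60, 1250),
            fs=2500.0, labels=("Oz",), window=(0.0, 0.5),
        )
        spec = es.multitaper_psd(epochs)
        res = es.find_knee(es.sliding_slopes(spec.freqs, spec.power[0], method="line"))
        assert abs(res.f_knee - oracle) <= 20.0
        # the generator's dip is designed to sit in the knee region
        assert 120.0 <= res.f_knee <= 220.0


class TestKneeTimescale:
    def test_175_hz(self):
        assert es.knee_timescale(175.0) == pytest.approx(9.09e-4, rel=1e-3)

    def test_identity_frequency(self):
        assert es.knee_timescale(1.0 / (2 * np.pi)) == pytest.approx(1.0, rel=1e-12)

    def test_inverse_proportionality(self):
        assert es.knee_timescale(200.0) == pytest.approx(es.knee_timescale(100.0) / 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            es.knee_timescale(0.0)
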