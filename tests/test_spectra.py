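"""Spectral chains: averaged periodograms, attenuation conversion,
band metrics and the 4PL cavitation-threshold fit."""

import numpy as np
import pytest

from sonobubble.spectra import (CavitationResponse, WaveformSet,
                                attenuation_spectrum, averaged_power_spectrum,
                                band_metrics, classify_regimes, fit_4pl,
                                four_param_logistic, resonance_peak)
from sonobubble.synthetic import gen_mi_response, gen_waveform_set


def _sine_set(f0=2e6, fs=40e6, n=2048, reps=1, role="sample"):
    t = np.arange(n) / fs
    w = np.tile(np.sin(2 * np.pi * f0 * t), (reps, 1))
    return WaveformSet(w, fs, role=role)


class TestAveragedSpectrum:
    def test_sinusoid_dominant_bin(self):
        f, p = averaged_power_spectrum(_sine_set())
        assert abs(f[np.argmax(p)] - 2e6) <= f[1] - f[0]

    def test_mean_of_identical_replicates_idempotent(self):
        one = _sine_set(reps=1)
        two = _sine_set(reps=2)
        f1, p1 = averaged_power_spectrum(one)
        f2, p2 = averaged_power_spectrum(two)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_white_noise_converges_to_flat(self):
        rng = np.random.default_rng(42)
        w = rng.standard_normal((400, 512))
        f, p = averaged_power_spectrum(WaveformSet(w, 10e6))
        interior = p[1:-1]      # skip DC and Nyquist (half-weight bins)
        db = 10 * np.log10(interior / interior.mean())
        assert np.abs(db).max() < 1.0


class TestAttenuation:
    def test_equal_sets_give_zero(self):
        s = _sine_set(reps=3)
        b = _sine_set(reps=3, role="baseline")
        spec = attenuation_spectrum(b, s)
        band = (spec.frequency > 1.9e6) & (spec.frequency < 2.1e6)
        assert np.allclose(spec.attenuation[band], 0.0, atol=1e-9)

    def test_sixteen_db_over_eight_cm(self):
        b = _sine_set(role="baseline")
        scaled = WaveformSet(b.waveforms * 10 ** (-16 / 20), b.sampling_rate)
        spec = attenuation_spectrum(b, scaled, path_cm=8.0)
        i = np.argmin(np.abs(spec.frequency - 2e6))
        assert spec.attenuation[i] == pytest.approx(2.0, abs=1e-9)

    def test_antisymmetric_under_role_swap(self):
        base, samp = gen_waveform_set(
            lambda f: 1.5 * np.exp(-((f - 3e6) / 1e6) ** 2), np.inf, 2, 0)
        fwd = attenuation_spectrum(base, samp)
        rev = attenuation_spectrum(
            WaveformSet(samp.waveforms, samp.sampling_rate, "baseline"),
            WaveformSet(base.waveforms, base.sampling_rate, "sample"))
        np.testing.assert_allclose(fwd.attenuation, -rev.attenuation,
                                   atol=1e-9)

    def test_grid_mismatch_rejected(self):
        b = _sine_set(n=2048, role="baseline")
        s = _sine_set(n=1024)
        with pytest.raises(ValueError, match="match"):
            attenuation_spectrum(b, s)


class TestResonancePeak:
    def test_flat_spectrum_tie_gives_lowest_frequency(self):
        from sonobubble.spectra import AttenuationSpectrum
        spec = AttenuationSpectrum(np.linspace(1e6, 5e6, 41), np.full(41, 2.0))
        f, a = resonance_peak(spec, (2e6, 4e6))
        assert f == pytest.approx(2e6)

    def test_generator_peak_recovered(self):
        prof = lambda f: 4.0 * np.exp(-0.5 * ((f - 2.78e6) / 0.5e6) ** 2)
        base, samp = gen_waveform_set(prof, np.inf, 3, 0)
        spec = attenuation_spectrum(base, samp)
        f, a = resonance_peak(spec, (1e6, 6e6))
        df = spec.frequency[1] - spec.frequency[0]
        assert abs(f - 2.78e6) <= df
        assert a == pytest.approx(4.00, abs=0.05)

    def test_edge_peak_returned_without_extrapolation(self):
        from sonobubble.spectra import AttenuationSpectrum
        freq = np.linspace(1e6, 5e6, 41)
        spec = AttenuationSpectrum(freq, np.linspace(0, 4, 41))
        f, a = resonance_peak(spec, (2e6, 5e6))
        assert f == pytest.approx(5e6) and a == pytest.approx(4.0)

    def test_empty_band_rejected(self):
        from sonobubble.spectra import AttenuationSpectrum
        spec = AttenuationSpectrum(np.linspace(1e6, 5e6, 41), np.zeros(41))
        with pytest.raises(ValueError):
            resonance_peak(spec, (8e6, 9e6))


class TestBandMetrics:
    def setup_method(self):
        self.f = np.linspace(0.0, 12e6, 1201)
        self.bg = np.ones_like(self.f)

    def test_identical_spectra_at_floor(self):
        sub, integ = band_metrics(self.f, self.bg, self.bg)
        assert sub == 0.0
        assert integ <= 10 * np.log10(1e-29)

    def test_injected_subharmonic_tone(self):
        s = self.bg.copy()
        s[np.argmin(np.abs(self.f - 500e3))] *= 100.0    # +20 dB
        sub, integ = band_metrics(self.f, s, self.bg)
        assert sub == pytest.approx(20.0, abs=1e-9)

    def test_out_of_band_tone_separates_metrics(self):
        s = self.bg.copy()
        s[np.argmin(np.abs(self.f - 3e6))] *= 100.0
        sub, integ = band_metrics(self.f, s, self.bg)
        assert sub == 0.0
        assert integ > -100.0

    def test_invariant_to_content_outside_both_bands(self):
        s = self.bg.copy()
        s[np.argmin(np.abs(self.f - 500e3))] *= 10.0
        s2 = s.copy()
        s2[self.f > 11e6] *= 1000.0
        assert band_metrics(self.f, s, self.bg) == \
            band_metrics(self.f, s2, self.bg)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="band"):
            band_metrics(np.linspace(1e6, 5e6, 100), np.ones(100),
                         np.ones(100))


class TestFourPL:
    def test_noiseless_recovery_to_high_precision(self):
        mi = np.linspace(0.01, 1.2, 26)
        r = gen_mi_response(0.0, -30.0, 8.0, 0.30, mi, 0.0, 1, 0, "x")
        fit = fit_4pl({"x": r})
        assert fit.threshold("x") == pytest.approx(0.30, rel=1e-6)
        assert fit.residual_rms < 1e-8
        assert not fit.flagged["x"]

    def test_joint_fit_shares_plateaus(self):
        mi = np.linspace(0.01, 1.2, 26)
        rs = {k: gen_mi_response(0.0, -30.0, 8.0, c, mi, 0.0, 1, i, k)
              for i, (k, c) in enumerate([("a", 0.2), ("b", 0.4)])}
        fit = fit_4pl(rs, share_plateaus=True)
        pa, pb = fit.params["a"], fit.params["b"]
        assert pa["a"] == pb["a"] and pa["d"] == pb["d"]
        assert pa["c"] == pytest.approx(0.2, rel=1e-4)
        assert pb["c"] == pytest.approx(0.4, rel=1e-4)

    def test_steplike_curve_located_by_grid_oracle(self):
        mi = np.linspace(0.05, 1.0, 20)
        a, d, b, c_true = 0.0, -30.0, 50.0, 0.42
        r = gen_mi_response(a, d, b, c_true, mi, 0.0, 1, 0, "x")
        # brute-force oracle: best step location on a fine grid
        y = r.response[0]
        cands = np.linspace(0.05, 1.0, 2000)
        sse = [np.sum((np.where(mi < cc, a, d) - y) ** 2) for cc in cands]
        c_oracle = cands[int(np.argmin(sse))]
        fit = fit_4pl({"x": r})
        spacing = mi[1] - mi[0]
        assert abs(fit.threshold("x") - c_oracle) <= spacing

    def test_threshold_ci_brackets_estimate(self):
        mi = np.linspace(0.01, 1.2, 26)
        r = gen_mi_response(0.0, -30.0, 8.0, 0.44, mi, 1.0, 3, 9, "x")
        fit = fit_4pl({"x": r})
        lo, hi = fit.conf_int("x")
        assert lo < fit.threshold("x") < hi

    def test_summary_mentions_threshold(self):
        mi = np.linspace(0.01, 1.2, 26)
        fit = fit_4pl({"x": gen_mi_response(0, -30, 8, 0.3, mi, 0, 1, 0, "x")})
        assert "0.300" in fit.summary()

    def test_too_few_mi_levels_rejected(self):
        with pytest.raises(ValueError, match="4"):
            CavitationResponse(np.array([0.1, 0.2, 0.3]), np.zeros(3))


class TestRegimes:
    def test_worked_boundaries(self):
        lo, hi = classify_regimes(8.0, 0.30)
        assert lo == pytest.approx(0.208, abs=5e-4)
        assert hi == pytest.approx(0.433, abs=5e-4)

    def test_geometric_symmetry(self):
        for b in (2.0, 5.0, 11.0):
            lo, hi = classify_regimes(b, 0.27)
            assert lo * hi == pytest.approx(0.27 ** 2, rel=1e-12)

    def test_steep_limit_collapses_to_c(self):
        lo, hi = classify_regimes(1e6, 0.5)
        assert lo == pytest.approx(0.5, rel=1e-4)
        assert hi == pytest.approx(0.5, rel=1e-4)
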