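"""Band-pass design, trough detection, windowed FFT and peak extraction."""

import numpy as np
import pytest

import hemophase as hp
from hemophase.errors import ConfigError, InsufficientSignalError

from conftest import make_sinusoid_window

FS = 100.0


def _t(duration, fs=FS):
    return np.arange(0, duration, 1 / fs)


class TestBandpass:
    def test_constant_input_rejected_to_zero(self):
        y = hp.bandpass(np.full(3000, 7.5), FS)
        assert np.max(np.abs(y)) < 1e-9

    def test_passband_tone_preserved(self):
        t = _t(30)
        y = hp.bandpass(np.sin(2 * np.pi * 1.2 * t), FS)
        amp = 0.5 * (y[200:-200].max() - y[200:-200].min())
        assert 0.94 <= amp <= 1.0

    def test_respiration_band_attenuated(self):
        t = _t(30)
        y = hp.bandpass(np.sin(2 * np.pi * 0.2 * t), FS)
        amp = 0.5 * (y[200:-200].max() - y[200:-200].min())
        assert -20 * np.log10(amp) >= 10.0

    def test_passband_above_nyquist_is_config_error(self):
        with pytest.raises(ConfigError):
            hp.design_bandpass(18.0, hp.PipelineConfig())

    def test_zero_phase_no_lag(self):
        t = _t(30)
        x = np.sin(2 * np.pi * 1.5 * t)
        y = hp.bandpass(x, FS)
        xs, ys = x[200:-200], y[200:-200]
        xc = np.correlate(ys, xs, mode="full")
        lag = int(np.argmax(xc)) - (xs.size - 1)
        assert lag == 0


class TestPulseBoundaries:
    def test_sinusoid_troughs_counted_and_located(self):
        # sin(2*pi*1.25 t) over 5 cycles: interior minima at 0.6 + 0.8k
        t = _t(4.0)
        x = np.sin(2 * np.pi * 1.25 * t)
        b = hp.detect_pulse_boundaries(x, FS)
        assert b.size == 5
        analytic = 0.6 + 0.8 * np.arange(5)
        assert np.max(np.abs(t[b] - analytic)) < 0.02
        w = hp.trim_to_boundaries(t, x, x, b)
        assert w.beat_count == 4
        assert abs((w.end_time - w.start_time) - 4 * 0.8) <= 1.5 / FS

    def test_flat_signal_is_insufficient(self):
        with pytest.raises(InsufficientSignalError):
            hp.detect_pulse_boundaries(np.zeros(1000), FS)

    def test_noisy_troughs_within_20ms(self):
        # band-passed first, as in the pipeline (detection pre-condition)
        rng = np.random.default_rng(0)
        t = _t(8.0)
        x = np.sin(2 * np.pi * 1.25 * t) + 0.01 * rng.standard_normal(t.size)
        xf = hp.bandpass(x, FS)
        b = hp.detect_pulse_boundaries(xf, FS)
        analytic = 0.6 + 0.8 * np.arange(10)
        interior = t[b][(t[b] > 0.5) & (t[b] < 7.5)]
        assert interior.size >= 7
        errs = [np.min(np.abs(analytic - td)) for td in interior]
        assert max(errs) < 0.02


class TestTrim:
    def test_idempotent_on_trimmed_input(self):
        t = _t(4.0)
        x = np.sin(2 * np.pi * 1.25 * t)
        b = hp.detect_pulse_boundaries(x, FS)
        w1 = hp.trim_to_boundaries(t, x, x, b)
        w2 = hp.trim_to_boundaries(w1.times, w1.n_hbo2, w1.n_hb, w1.boundaries)
        assert np.allclose(w1.n_hbo2, w2.n_hbo2, atol=1e-12)
        assert w1.start_time == w2.start_time

    def test_mean_removed(self):
        t = _t(4.0)
        x = 3.0 + np.sin(2 * np.pi * 1.25 * t)
        b = hp.detect_pulse_boundaries(x - x.mean(), FS)
        w = hp.trim_to_boundaries(t, x, x, b)
        assert abs(w.n_hbo2.mean()) < 1e-6 * 1.0


class TestSpectrum:
    def test_power_of_two_resampling_and_resolution(self):
        w = make_sinusoid_window(n=400, sample_rate=100.0)
        spec = hp.spectrum(w)
        assert spec.n_fft == 512
        span = w.end_time - w.start_time
        df = spec.frequencies[1] - spec.frequencies[0]
        assert df == pytest.approx(1.0 / span, rel=0.01)

    def test_power_of_two_length_unchanged(self):
        w = make_sinusoid_window(n=512, sample_rate=128.0)
        assert hp.spectrum(w).n_fft == 512

    def test_parseval_identity(self):
        w = make_sinusoid_window(n=400, sample_rate=100.0, dtheta=0.1)
        spec = hp.spectrum(w)
        x = spec.resampled_hbo2
        n = spec.n_fft
        mag2 = np.abs(spec.spec_hbo2) ** 2
        # rfft of even-length real input: double interior bins
        spec_energy = (mag2[0] + 2 * mag2[1:-1].sum() + mag2[-1]) / n
        assert spec_energy == pytest.approx(np.sum(x**2), rel=1e-6)


class TestMainPeak:
    def test_exact_bin_selection(self):
        # 512 samples at 128 Hz: df = 0.25 Hz, 1.25 Hz is exactly bin 5
        w = make_sinusoid_window(freq_hz=1.25, sample_rate=128.0, n=512)
        peak = hp.main_peak(hp.spectrum(w))
        assert peak.bin_index == 5
        assert peak.frequency == pytest.approx(1.25)
        assert peak.a_hbo2 == pytest.approx(1.0, rel=1e-6)
        assert peak.a_hb == pytest.approx(0.5, rel=1e-6)

    def test_white_noise_has_low_snr(self):
        rng = np.random.default_rng(3)
        t = np.arange(512) / 128.0
        x = rng.standard_normal(512)
        w = hp.AnalysisWindow(0.0, float(t[-1]), t, x - x.mean(), x - x.mean(),
                              np.array([0, 511]), 4)
        peak = hp.main_peak(hp.spectrum(w))
        assert peak.snr < hp.PipelineConfig().snr_min

    def test_fundamental_beats_weak_harmonic(self):
        t = np.arange(512) / 128.0
        x = np.sin(2 * np.pi * 1.25 * t) + 0.3 * np.sin(2 * np.pi * 2.5 * t)
        w = hp.AnalysisWindow(0.0, float(t[-1]), t, x - x.mean(), x - x.mean(),
                              np.array([0, 511]), 4)
        peak = hp.main_peak(hp.spectrum(w))
        assert peak.frequency == pytest.approx(1.25)


class TestPhaseInvariance:
    @pytest.mark.parametrize("shift_s", [0.0, 0.013, 0.21, 0.404])
    def test_time_shift_leaves_phase_difference_invariant(self, shift_s):
        """Delaying both channels shifts each phase identically."""
        ref = make_sinusoid_window(dtheta=0.1, t0=0.0)
        shifted = make_sinusoid_window(dtheta=0.1, t0=shift_s)
        d_ref = hp.compute_phase_delay(hp.main_peak(hp.spectrum(ref)))
        d_shift = hp.compute_phase_delay(hp.main_peak(hp.spectrum(shifted)))
        assert abs(d_ref - d_shift) < 1e-9

    def test_amplitude_fidelity_noiseless_on_bin(self):
        w = make_sinusoid_window(freq_hz=1.25, sample_rate=128.0, n=512,
                                 a_hbo2=0.04, a_hb=0.005, dtheta=0.08)
        peak = hp.main_peak(hp.spectrum(w))
        assert abs(peak.a_hbo2 - 0.04) / 0.04 < 0.01
        assert abs(peak.a_hb - 0.005) / 0.005 < 0.01
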