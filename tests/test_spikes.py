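"""Filtering and threshold-detection behaviour against analytic oracles."""

import numpy as np
import pytest
from scipy import signal as sps

from mea_nmj import (
    FilterSettings,
    RawRecording,
    bandpass_filter,
    detect_spikes,
    gen_raw_recording,
)
from conftest import crossing_scan_oracle, spaced_times

FS = 10_000.0


def _sine_recording(freq_hz, duration=2.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return RawRecording(["E1"], fs, np.sin(2 * np.pi * freq_hz * t)[None, :])


def _independent_gain(freq_hz, fs=FS, order=4, low=300.0, high=3_000.0, zero_phase=True):
    """Analytic magnitude of the Butterworth design, computed directly."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq_hz / fs])
    g = abs(h[0])
    return g * g if zero_phase else g


class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        rec = RawRecording(["E1"], FS, np.zeros((1, 1000)))
        out = bandpass_filter(rec)
        assert np.all(out.samples == 0)
        assert out.samples.shape == rec.samples.shape

    @pytest.mark.parametrize(
        "freq,rtol",
        [(1_000.0, 0.02), (50.0, 0.05)],
        ids=["passband-1kHz", "stopband-50Hz"],
    )
    def test_steady_state_sine_gain_matches_analytic_response(self, freq, rtol):
        out = bandpass_filter(_sine_recording(freq)).samples[0]
        # quadrature demodulation over the central second (transients decayed)
        t = np.arange(out.size) / FS
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        c = np.cos(2 * np.pi * freq * t[mid])
        s = np.sin(2 * np.pi * freq * t[mid])
        amp = 2 * np.hypot(np.mean(out[mid] * c), np.mean(out[mid] * s))
        expected = _independent_gain(freq)
        assert amp == pytest.approx(expected, rel=rtol)

    def test_single_pass_mode_uses_unsquared_gain(self):
        settings = FilterSettings(zero_phase=False)
        out = bandpass_filter(_sine_recording(1_000.0), settings).samples[0]
        t = np.arange(out.size) / FS
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        amp = 2 * np.hypot(
            np.mean(out[mid] * np.cos(2 * np.pi * 1_000 * t[mid])),
            np.mean(out[mid] * np.sin(2 * np.pi * 1_000 * t[mid])),
        )
        assert amp == pytest.approx(_independent_gain(1_000.0, zero_phase=False), rel=0.02)

    def test_nyquist_violation_reports_offending_values(self):
        rec = RawRecording(["E1"], 4_000.0, np.zeros((1, 100)))
        with pytest.raises(ValueError, match="3000.*4000"):
            bandpass_filter(rec, FilterSettings())

    def test_deterministic_and_shape_preserving(self, rng):
        rec = RawRecording(["A", "B"], FS, rng.normal(size=(2, 5_000)))
        a = bandpass_filter(rec).samples
        b = bandpass_filter(rec).samples
        np.testing.assert_array_equal(a, b)
        assert a.shape == (2, 5_000)


class TestDetectSpikes:
    def test_zero_trace_gives_empty_train(self):
        rec = RawRecording(["E1"], FS, np.zeros((1, 1000)))
        sts = detect_spikes(rec)
        assert sts.trains["E1"].size == 0

    def test_noise_free_waveforms_at_ten_sd_detected_once_each(self, rng):
        # spike density tuned so the waveform peak sits ~10x the trace SD:
        # only the two main lobes (0.75 ms apart) cross a 7 SD threshold
        # and the dead time collapses them to one timestamp per spike.
        duration, n_spikes = 20.0, 260
        times = spaced_times(rng, n_spikes, duration)
        rec, _ = gen_raw_recording(
            {"E1": times}, noise_sd=0.0, amplitude_uv=40.0, fs=FS, duration=duration, seed=0
        )
        filtered = bandpass_filter(rec)
        peak = np.max(np.abs(filtered.samples[0]))
        assert 8 < peak / filtered.samples[0].std() < 14  # fixture sanity
        sts = detect_spikes(filtered, threshold_sd=7.0, dead_time=1e-3)
        det = sts.trains["E1"]
        assert det.size == n_spikes
        assert np.max(np.abs(det - times)) < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_crossing_scan_oracle_on_noisy_traces(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 5, size=20_000)
        x[rng.integers(0, x.size, 20)] += rng.choice([-1, 1], 20) * 60
        rec = RawRecording(["E1"], FS, x[None, :])
        for polarity in ("both", "negative"):
            sts = detect_spikes(rec, threshold_sd=4.0, dead_time=2e-3, polarity=polarity)
            oracle = crossing_scan_oracle(x, FS, 4.0, 2e-3, polarity)
            np.testing.assert_allclose(sts.trains["E1"], oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_offset_and_positive_scale_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 5, size=10_000)
        x[::977] += 80
        rec = RawRecording(["E1"], FS, x[None, :])
        base = detect_spikes(rec, threshold_sd=5.0).trains["E1"]
        shifted = detect_spikes(
            RawRecording(["E1"], FS, (x + 123.4)[None, :]), threshold_sd=5.0
        ).trains["E1"]
        scaled = detect_spikes(
            RawRecording(["E1"], FS, (x * 7.7)[None, :]), threshold_sd=5.0
        ).trains["E1"]
        np.testing.assert_array_equal(base, shifted)
        np.testing.assert_array_equal(base, scaled)

    def test_pure_noise_false_positives_match_analytic_tail_bound(self):
        # per-sample two-sided exceedance at 7 SD: p = 2*Phi(-7) ~ 2.6e-12;
        # over 50 seeds x 2 electrodes x 5 s x 10 kHz (5e6 samples) the
        # expected count is ~1.3e-5, so a Poisson bound allows at most ~2.
        from scipy.stats import norm

        total_samples = 0
        total_fp = 0
        for seed in range(50):
            rec, _ = gen_raw_recording(
                {"E1": [], "E2": []}, noise_sd=5.0, fs=FS, duration=5.0, seed=seed
            )
            filtered = bandpass_filter(rec)
            sts = detect_spikes(filtered, threshold_sd=7.0)
            total_fp += sts.n_spikes
            total_samples += filtered.samples.size
        expected = 2 * norm.sf(7.0) * total_samples
        assert expected < 1e-3
        assert total_fp <= 2

    def test_constant_trace_warns_and_returns_empty(self, caplog):
        rec = RawRecording(["E1"], FS, np.full((1, 1000), 3.3))
        with caplog.at_level("WARNING", logger="mea_nmj.spikes"):
            sts = detect_spikes(rec)
        assert sts.trains["E1"].size == 0
        assert "SD=0" in caplog.text

    def test_negative_polarity_ignores_positive_excursions(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10_000)
        x[2_000] += 30
        x[6_000] -= 30
        rec = RawRecording(["E1"], FS, x[None, :])
        sts = detect_spikes(rec, threshold_sd=6.0, polarity="negative")
        assert sts.trains["E1"].size == 1
        assert sts.trains["E1"][0] == pytest.approx(0.6, abs=1e-3)
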