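"""Detection, level measurement, TDOA estimation and call association."""

import numpy as np
import pytest

from batgaze.frontend import (DetectorParams, associate_detections, bandpass,
                              detect_calls, measure_level, tdoa_pair)
from batgaze.simulate import ChirpParams, synthesize_chirp

FS = 250_000.0


def make_noise(n, level_db=-65.0, seed=0):
    return np.random.default_rng(seed).standard_normal(n) * 10 ** (level_db / 20)


class TestDetection:
    def test_pure_noise_yields_nothing(self):
        dets = detect_calls(make_noise(int(0.5 * FS)), FS,
                            DetectorParams(threshold_db=12.0))
        assert dets == []

    def test_empty_waveform(self):
        assert detect_calls(np.array([]), FS) == []

    def test_noiseless_render_count_and_onsets(self, rt_quiet_flight, mics):
        """Every scheduled call detected once, onsets within 0.5 ms of truth."""
        wave, truth = rt_quiet_flight
        ch = 3
        dets = detect_calls(wave[ch], FS)
        assert len(dets) == truth.n_calls
        src = truth.calls[["x_m", "y_m"]].to_numpy()
        r = np.sqrt(np.sum((np.column_stack([src, np.full(len(src), 1.2)])
                            - mics.mic_positions[ch]) ** 2, axis=1))
        expected = truth.calls["emission_time_s"].to_numpy() + r / 344.0
        got = np.array([d.onset_time_s for d in dets])
        assert np.max(np.abs(np.sort(got) - np.sort(expected))) < 0.5e-3

    def test_doublet_with_small_gap_gives_two(self):
        chirp = synthesize_chirp(ChirpParams(), FS)
        x = make_noise(int(0.2 * FS), -80.0)
        for t0 in (0.05, 0.07):
            i = int(t0 * FS)
            x[i:i + len(chirp)] += chirp * 10 ** (-30 / 20)
        dets = detect_calls(x, FS, DetectorParams(min_gap_ms=5.0))
        assert len(dets) == 2

    def test_close_pulses_merged_below_min_gap(self):
        chirp = synthesize_chirp(ChirpParams(duration_ms=2.0), FS)
        x = make_noise(int(0.2 * FS), -80.0)
        for t0 in (0.05, 0.053):
            i = int(t0 * FS)
            x[i:i + len(chirp)] += chirp * 10 ** (-30 / 20)
        dets = detect_calls(x, FS, DetectorParams(min_gap_ms=8.0))
        assert len(dets) == 1

    def test_onset_not_after_peak(self, rt_flight):
        wave, _ = rt_flight
        for d in detect_calls(wave[0], FS):
            assert d.onset_time_s <= d.peak_time_s


class TestMeasureLevel:
    def test_sine_rms(self):
        t = np.arange(int(0.05 * FS)) / FS
        a = 0.3
        x = a * np.sin(2 * np.pi * 40_000 * t)
        lvl = measure_level(x, (0.01, 0.04), fs_hz=FS)
        assert lvl == pytest.approx(20 * np.log10(a / np.sqrt(2)), abs=0.1)

    def test_amplitude_doubling(self):
        t = np.arange(int(0.05 * FS)) / FS
        x = np.sin(2 * np.pi * 40_000 * t)
        l1 = measure_level(0.1 * x, (0.01, 0.04), fs_hz=FS)
        l2 = measure_level(0.2 * x, (0.01, 0.04), fs_hz=FS)
        assert l2 - l1 == pytest.approx(6.0206, abs=0.01)

    def test_dc_offset_invariance(self):
        t = np.arange(int(0.05 * FS)) / FS
        x = 0.2 * np.sin(2 * np.pi * 40_000 * t)
        l0 = measure_level(x, (0.01, 0.04), fs_hz=FS)
        l1 = measure_level(x + 0.5, (0.01, 0.04), fs_hz=FS)
        assert l1 == pytest.approx(l0, abs=0.05)

    def test_chirp_matches_psd_integration_oracle(self):
        """Band-limited RMS vs direct integration of the periodogram."""
        from scipy.signal import periodogram

        chirp = synthesize_chirp(ChirpParams(source_level_db=-20.0), FS)
        x = np.zeros(int(0.02 * FS))
        x[1000:1000 + len(chirp)] = chirp
        lvl = measure_level(x, (0.0, 0.02), fs_hz=FS)
        f, psd = periodogram(x, FS)
        band = (f >= 20_000) & (f <= 80_000)
        oracle = 10 * np.log10(np.trapezoid(psd[band], f[band]))
        assert lvl == pytest.approx(oracle, abs=0.2)

    def test_window_guards(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError):
            measure_level(x, (0.0, 1.0), fs_hz=FS)
        with pytest.raises(ValueError):
            measure_level(np.zeros(100_000), (0.0, 0.00002), fs_hz=FS)


class TestTdoa:
    def test_identical_signals_zero_lag(self):
        x = bandpass(make_noise(4096, -20.0, 1), FS)
        tdoa, peak = tdoa_pair(x, x, FS, 1e-3)
        assert tdoa == pytest.approx(0.0, abs=1e-7)
        assert peak == pytest.approx(1.0, abs=1e-6)

    def test_integer_shift(self):
        x = bandpass(make_noise(4096, -20.0, 2), FS)
        y = np.roll(x, 10)
        tdoa, _ = tdoa_pair(x, y, FS, 1e-3)
        assert tdoa == pytest.approx(10 / FS, abs=0.5 / FS)

    @pytest.mark.parametrize("method", ["cc", "gcc_phat"])
    def test_noisy_chirp_vs_exhaustive_lag_oracle(self, method):
        """Sub-sample fractional delay recovered within one sample; integer
        part agrees with a brute-force dot-product search over all lags."""
        rng = np.random.default_rng(5)
        chirp = synthesize_chirp(ChirpParams(), FS)
        true_delay = 173.2e-6
        n = 4096
        a = np.zeros(n)
        a[500:500 + len(chirp)] = chirp
        # fractional shift via FFT phase ramp
        freqs = np.fft.rfftfreq(n, 1 / FS)
        b = np.fft.irfft(np.fft.rfft(a) * np.exp(-2j * np.pi * freqs * true_delay), n)
        snr_scale = 10 ** (-10 / 20) * np.std(a[500:1250])
        a = a + rng.standard_normal(n) * snr_scale
        b = b + rng.standard_normal(n) * snr_scale
        a, b = bandpass(a, FS), bandpass(b, FS)
        tdoa, _ = tdoa_pair(a, b, FS, 1e-3, method=method)
        assert tdoa == pytest.approx(true_delay, abs=1.0 / FS)
        # exhaustive integer-lag oracle
        lags = np.arange(-250, 251)
        scores = [np.dot(a, np.roll(b, -L)) for L in lags]
        best = lags[int(np.argmax(scores))]
        assert round(tdoa * FS) == pytest.approx(best, abs=1)

    def test_antisymmetry(self):
        x = bandpass(make_noise(4096, -20.0, 3), FS)
        y = np.roll(x, 7)
        t_ab, _ = tdoa_pair(x, y, FS, 1e-3)
        t_ba, _ = tdoa_pair(y, x, FS, 1e-3)
        assert t_ab == pytest.approx(-t_ba, abs=0.1 / FS)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            tdoa_pair(np.zeros(100), np.ones(100), FS, 1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tdoa_pair(np.ones(100), np.ones(99), FS, 1e-3)


class TestAssociation:
    def test_noiseless_flight_groups_all_channels(self, rt_quiet_flight, mics):
        wave, truth = rt_quiet_flight
        per_mic = {int(m): detect_calls(wave[i], FS, mic_id=int(m))
                   for i, m in enumerate(mics.mic_ids)}
        groups, residual = associate_detections(per_mic, mics)
        assert len(groups) == truth.n_calls
        assert all(len(g) == len(mics) for g in groups)
        assert residual == []

    def test_muted_channel_keeps_call(self, rt_quiet_flight, mics):
        wave, truth = rt_quiet_flight
        per_mic = {int(m): detect_calls(wave[i], FS, mic_id=int(m))
                   for i, m in enumerate(mics.mic_ids)}
        per_mic[int(mics.mic_ids[4])] = []
        groups, _ = associate_detections(per_mic, mics)
        assert len(groups) == truth.n_calls
        assert all(len(g) == len(mics) - 1 for g in groups)

    def test_two_calls_not_cross_assigned(self, mics, room_straight):
        """Two renders 30 ms apart stay two groups."""
        import pandas as pd

        from batgaze.beam import BeamModel
        from batgaze.propagation import Environment
        from batgaze.simulate import render_mics

        calls = pd.DataFrame({
            "call_index": [0, 1], "emission_time_s": [0.02, 0.05],
            "x_m": [2.0, 2.06], "y_m": [2.4, 2.4], "beam_aim_deg": [0.0, 0.0]})
        wave = render_mics(calls, ChirpParams(), BeamModel.calibrated(), mics,
                           Environment(noise_db=-120.0), room_straight, seed=0)
        per_mic = {int(m): detect_calls(wave[i], FS, mic_id=int(m))
                   for i, m in enumerate(mics.mic_ids)}
        groups, _ = associate_detections(per_mic, mics)
        assert len(groups) == 2
        spans = [max(d.peak_time_s for d in g.values())
                 - min(d.peak_time_s for d in g.values()) for g in groups]
        assert all(s < 0.015 for s in spans)
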