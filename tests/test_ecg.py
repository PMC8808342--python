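"""ECG chain: filtering, windowing, two-round peak detection, window validation."""

import numpy as np
import pytest

from nighthrv import (
    PeakSeries,
    WaveformRecord,
    bandpass,
    detect_peaks_round1,
    detect_peaks_round2,
    segment_windows,
    synthesize_ecg,
    validate_window,
)

from conftest import bare_ecg_spec, clean_ecg_spec, match_peaks

FS = 512.0


def sine_record(freq_hz, duration_s=60.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return WaveformRecord(samples=np.sin(2 * np.pi * freq_hz * t), sampling_rate_hz=fs)


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = WaveformRecord(samples=np.zeros(4096), sampling_rate_hz=FS)
        np.testing.assert_allclose(bandpass(rec).samples, 0.0)

    def test_stopband_wander_attenuated(self):
        out = bandpass(sine_record(0.05, duration_s=120.0))
        mid = out.samples[len(out.samples) // 4 : -len(out.samples) // 4]
        assert np.abs(mid).max() < 0.1  # > 90% attenuation at 0.05 Hz

    def test_passband_preserved(self):
        out = bandpass(sine_record(10.0))
        mid = out.samples[2048:-2048]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_high_cutoff_above_nyquist_errors(self):
        rec = WaveformRecord(samples=np.zeros(1024), sampling_rate_hz=128.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, high_hz=100.0)


class TestSegmentation:
    def test_mean_night_duration_yields_99_windows(self):
        # 8.25 h at a light 4 Hz stand-in rate: floor(8.25*3600/300) = 99
        rec = WaveformRecord(samples=np.zeros(int(8.25 * 3600 * 4)), sampling_rate_hz=4.0)
        assert len(segment_windows(rec)) == 99

    def test_sub_window_record_gives_empty_list(self):
        rec = WaveformRecord(samples=np.zeros(int(299 * FS)), sampling_rate_hz=FS)
        assert segment_windows(rec) == []

    def test_two_windows_tile_without_overlap(self):
        rec = WaveformRecord(samples=np.arange(int(600 * 4.0)), sampling_rate_hz=4.0)
        wins = segment_windows(rec)
        assert len(wins) == 2
        assert wins[0].start_time_s == 0.0 and wins[1].start_time_s == 300.0
        np.testing.assert_array_equal(
            np.concatenate([wins[0].samples, wins[1].samples]), rec.samples
        )


class TestRound1:
    def test_superset_of_true_r_peaks(self):
        wave, truth = synthesize_ecg(clean_ecg_spec(60.0, 300.0))
        win = segment_windows(bandpass(wave))[0]
        r1 = detect_peaks_round1(win)
        assert len(r1) >= 300
        # every true beat has a round-1 peak within 1 sample
        d = np.abs(r1.times_s[:, None] - truth.true_beat_times_s[None, :])
        assert (d.min(axis=0) <= 1.5 / FS).all()

    def test_flat_window_is_empty(self):
        win = WaveformRecord(samples=np.zeros(1024), sampling_rate_hz=FS)
        assert len(detect_peaks_round1(win)) == 0

    def test_only_r_spikes_above_mean_detected(self):
        # negative sawtooth background below its mean except narrow R spikes
        wave, truth = synthesize_ecg(bare_ecg_spec(60.0, 60.0))
        x = wave.samples - 0.5  # everything except R tips below zero
        win = WaveformRecord(samples=x, sampling_rate_hz=FS)
        r1 = detect_peaks_round1(win)
        sens, ppv, _ = match_peaks(r1.times_s, truth.true_beat_times_s, tol_s=0.01)
        assert sens == 1.0 and ppv == 1.0


class TestRound2:
    def detect(self, wave):
        win = segment_windows(bandpass(wave))[0]
        r1 = detect_peaks_round1(win)
        return win, r1, detect_peaks_round2(win, r1)

    def test_clean_ecg_with_t_waves_found_exactly(self):
        wave, truth = synthesize_ecg(clean_ecg_spec(60.0, 300.0))
        _, _, r2 = self.detect(wave)
        assert len(r2) == 300
        sens, ppv, mae = match_peaks(r2.times_s, truth.true_beat_times_s, tol_s=0.01)
        assert sens == 1.0 and ppv == 1.0
        assert mae <= 1.0 / FS

    def test_attenuated_beat_restored_by_search_back(self):
        wave, truth = synthesize_ecg(bare_ecg_spec(60.0, 300.0))
        x = wave.samples.copy()
        b = truth.true_beat_times_s[150]
        seg = slice(int((b - 0.1) * FS), int((b + 0.1) * FS))
        x[seg] *= 0.4  # below theta x mean amplitude, above theta_prime
        win = WaveformRecord(samples=x, sampling_rate_hz=FS)
        r1 = detect_peaks_round1(win)
        r2 = detect_peaks_round2(win, r1)
        assert len(r2) == 300 and r2.n_added >= 1
        assert np.diff(r2.times_s).max() <= 1.2 + 1e-9

    def test_noise_spikes_inside_refractory_removed(self):
        wave, truth = synthesize_ecg(bare_ecg_spec(60.0, 300.0))
        x = wave.samples.copy()
        for b in truth.true_beat_times_s[[50, 120]]:
            i = int((b + 0.1) * FS)
            x[i] += 0.6  # spike 100 ms after the true R peak
        win = WaveformRecord(samples=x, sampling_rate_hz=FS)
        r2 = detect_peaks_round2(win, detect_peaks_round1(win))
        sens, ppv, _ = match_peaks(r2.times_s, truth.true_beat_times_s, tol_s=0.01)
        assert len(r2) == 300 and sens == 1.0 and ppv == 1.0

    def test_idempotent_on_own_output(self):
        wave, _ = synthesize_ecg(clean_ecg_spec(60.0, 300.0))
        win, _, r2 = self.detect(wave)
        again = detect_peaks_round2(win, r2)
        np.testing.assert_array_equal(again.indices, r2.indices)

    def test_output_subset_of_round1(self):
        wave, _ = synthesize_ecg(clean_ecg_spec(90.0, 300.0))
        _, r1, r2 = self.detect(wave)
        assert np.isin(r2.indices, r1.indices).all()

    def test_invariant_to_amplitude_scaling(self):
        wave, _ = synthesize_ecg(clean_ecg_spec(60.0, 300.0))
        win = segment_windows(bandpass(wave))[0]
        scaled = WaveformRecord(samples=win.samples * 37.5, sampling_rate_hz=FS)
        a = detect_peaks_round2(win, detect_peaks_round1(win))
        b = detect_peaks_round2(scaled, detect_peaks_round1(scaled))
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_empty_round1_gives_empty_series(self):
        win = WaveformRecord(samples=np.zeros(1024), sampling_rate_hz=FS)
        assert len(detect_peaks_round2(win, detect_peaks_round1(win))) == 0


def peaks_at(times_s, fs=100.0, n=None):
    idx = (np.asarray(times_s) * fs).astype(int)
    n = n or int(idx[-1] + fs)
    rec = WaveformRecord(samples=np.zeros(n), sampling_rate_hz=fs)
    return rec, PeakSeries.from_indices(rec, idx)


class TestValidateWindow:
    def test_clean_window_fully_valid(self):
        wave, _ = synthesize_ecg(clean_ecg_spec(60.0, 300.0))
        win = segment_windows(bandpass(wave))[0]
        r2 = detect_peaks_round2(win, detect_peaks_round1(win))
        q = validate_window(win, r2)
        assert q.is_valid and q.fraction_rr_in_range == 1.0 and q.reject_reason == ""

    def test_tachycardic_rhythm_rejected(self):
        rec, peaks = peaks_at(np.arange(100) * 0.24)  # 250 bpm
        q = validate_window(rec, peaks)
        assert not q.is_valid and q.reject_reason == "HR out of range"

    def test_dropout_heavy_window_rejected_by_fraction(self):
        # 70% normal beats at ~857 ms, 30% replaced by 2000 ms dropout gaps
        t, times = 0.0, [0.0]
        for k in range(100):
            t += 2.0 if k % 10 < 3 else 0.857
            times.append(t)
        rec, peaks = peaks_at(times)
        q = validate_window(rec, peaks)
        assert not q.is_valid
        assert q.reject_reason == "too many out-of-range RR intervals"
        assert q.fraction_rr_in_range == pytest.approx(0.7)

    def test_single_peak_insufficient(self):
        rec, peaks = peaks_at([1.0])
        q = validate_window(rec, peaks)
        assert not q.is_valid and q.reject_reason == "insufficient peaks"
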