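"""HRV parameter extraction: time domain, frequency domain, gating, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nighthrv import (
    HRVWindow,
    NNSeries,
    TachogramSpec,
    frequency_domain,
    gate_wearable_window,
    generate_tachogram,
    nightly_average,
    nn_from_peaks,
    time_domain,
)
from nighthrv.ecg import PeakSeries, WaveformRecord, WindowQuality, validate_window


def series(nn_ms, valid=None, source="ecg"):
    nn_ms = np.asarray(nn_ms, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(nn_ms) / 1000.0])
    return NNSeries(beat_times_s=times, nn_ms=nn_ms,
                    valid=np.ones(nn_ms.size, bool) if valid is None else np.asarray(valid, bool),
                    source=source)


def brute_force_time_domain(nn_values):
    """Independent plain-Python oracle for the four time-domain statistics."""
    n = len(nn_values)
    avnn = sum(nn_values) / n
    sdnn = math.sqrt(sum((x - avnn) ** 2 for x in nn_values) / (n - 1))
    diffs = [nn_values[k + 1] - nn_values[k] for k in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = sum(1 for d in diffs if abs(d) > 50.0) / n
    return {"avnn_ms": avnn, "hr_bpm": 60000.0 / avnn, "sdnn_ms": sdnn,
            "rmssd_ms": rmssd, "pnn50": pnn50}


class TestTimeDomain:
    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 60))
            vals = rng.uniform(400.0, 1150.0, n)
            got = time_domain(series(vals))
            want = brute_force_time_domain(list(vals))
            for key, v in want.items():
                assert got[key] == pytest.approx(v, rel=1e-9), key

    def test_hand_worked_example(self):
        got = time_domain(series([800.0, 860.0, 870.0, 805.0]))
        assert got["avnn_ms"] == pytest.approx(833.75)
        assert got["rmssd_ms"] == pytest.approx(math.sqrt((60**2 + 10**2 + 65**2) / 3), abs=1e-9)
        assert got["rmssd_ms"] == pytest.approx(51.4, abs=0.1)
        assert got["pnn50"] == pytest.approx(0.5)

    def test_constant_series(self):
        got = time_domain(series([1000.0] * 300))
        assert got["hr_bpm"] == pytest.approx(60.0)
        assert got["rmssd_ms"] == 0.0 and got["sdnn_ms"] == 0.0 and got["pnn50"] == 0.0
        assert got["avnn_ms"] == 1000.0

    def test_two_interval_series(self):
        got = time_domain(series([900.0, 1100.0]))
        assert got["avnn_ms"] == pytest.approx(1000.0)
        assert got["hr_bpm"] == pytest.approx(60.0)

    def test_empty_nn_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            time_domain(series([800.0, 900.0], valid=[False, False]))

    @given(st.floats(-200.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, shift):
        base = np.array([780.0, 910.0, 850.0, 990.0, 870.0, 820.0])
        a = time_domain(series(base))
        b = time_domain(series(base + shift))
        assert b["rmssd_ms"] == pytest.approx(a["rmssd_ms"], abs=1e-9)
        assert b["sdnn_ms"] == pytest.approx(a["sdnn_ms"], abs=1e-9)
        assert b["avnn_ms"] == pytest.approx(a["avnn_ms"] + shift, abs=1e-9)

    @given(st.lists(st.floats(320.0, 1180.0), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_pnn50_is_a_proportion(self, vals):
        p = time_domain(series(vals))["pnn50"]
        assert 0.0 <= p <= 1.0
        if all(abs(b - a) <= 50.0 for a, b in zip(vals, vals[1:])):
            assert p == 0.0


class TestNNFromPeaks:
    def quality(self, wid=0.0):
        return WindowQuality(window_id=wid, n_peaks=4, n_removed=0, n_added=0,
                             fraction_rr_in_range=1.0, mean_hr_bpm=60.0, is_valid=True)

    def peaks(self, times):
        times = np.asarray(times, dtype=float)
        rec = WaveformRecord(samples=np.zeros(int(times[-1] * 100) + 200), sampling_rate_hz=100.0)
        return PeakSeries.from_indices(rec, (times * 100).astype(int))

    def test_uniform_peaks(self):
        nn = nn_from_peaks(self.peaks([0, 1, 2, 3]), self.quality())
        np.testing.assert_allclose(nn.nn_ms, [1000.0, 1000.0, 1000.0])
        assert nn.valid.all()

    def test_out_of_range_interval_breaks_adjacency(self):
        nn = nn_from_peaks(self.peaks([0.0, 0.8, 2.6, 3.4]), self.quality())
        np.testing.assert_allclose(nn.nn_ms, [800.0, 1800.0, 800.0])
        np.testing.assert_array_equal(nn.valid, [True, False, True])
        got = time_domain(nn)
        assert got["avnn_ms"] == pytest.approx(800.0)
        assert math.isnan(got["rmssd_ms"])  # no adjacent valid pair remains

    def test_single_peak_errors(self):
        with pytest.raises(ValueError, match="two peaks"):
            nn_from_peaks(self.peaks([1.0]), self.quality())

    def test_invalid_window_rejected(self):
        rec = WaveformRecord(samples=np.zeros(200), sampling_rate_hz=100.0)
        bad = validate_window(rec, PeakSeries.from_indices(rec, np.array([10])))
        with pytest.raises(ValueError, match="insufficient"):
            nn_from_peaks(self.peaks([0, 1, 2]), bad)


class TestFrequencyDomain:
    def tachogram(self, **kw):
        spec = TachogramSpec(duration_s=300.0, jitter_sd_ms=0.0, **kw)
        return generate_tachogram(spec)[0]

    def test_constant_series_has_no_band_power(self):
        nn = series([1000.0] * 300)
        fd = frequency_domain(nn)
        assert fd["lf_ms2"] < 1e-6 * 1000.0**2
        assert fd["hf_ms2"] < 1e-6 * 1000.0**2
        assert math.isnan(fd["lf_hf"])  # HF ~ 0 -> ratio undefined, not inf

    def test_lf_sinusoid_recovered(self):
        nn = self.tachogram(lf_amp_ms=50.0, lf_freq_hz=0.1, hf_amp_ms=0.0)
        fd = frequency_domain(nn)
        assert fd["lf_ms2"] / (fd["lf_ms2"] + fd["hf_ms2"]) > 0.9
        assert fd["lf_ms2"] == pytest.approx(50.0**2 / 2, rel=0.10)

    def test_hf_sinusoid_recovered(self):
        nn = self.tachogram(lf_amp_ms=0.0, hf_amp_ms=50.0, hf_freq_hz=0.25)
        fd = frequency_domain(nn)
        assert fd["hf_ms2"] / (fd["lf_ms2"] + fd["hf_ms2"]) > 0.9
        assert fd["hf_ms2"] == pytest.approx(50.0**2 / 2, rel=0.10)

    def test_welch_estimator_agrees_on_clean_sinusoid(self):
        nn = self.tachogram(lf_amp_ms=50.0, lf_freq_hz=0.1, hf_amp_ms=0.0)
        fd = frequency_domain(nn, estimator="welch")
        assert fd["lf_ms2"] == pytest.approx(50.0**2 / 2, rel=0.25)

    def test_short_series_errors(self):
        with pytest.raises(ValueError, match="frequency-domain"):
            frequency_domain(series([800.0] * 10))


class TestGate:
    @pytest.mark.parametrize("n_valid,retained", [(29, False), (30, True), (100, True)])
    def test_boundary_inclusive_at_30_percent(self, n_valid, retained):
        valid = np.zeros(100, bool)
        valid[:n_valid] = True
        nn = series([800.0] * 100, valid=valid, source="wearable")
        assert gate_wearable_window(nn, threshold=0.30) is retained

    def test_empty_window_gated_out(self):
        nn = NNSeries(np.array([0.0]), np.empty(0), np.empty(0, bool), "wearable")
        assert not gate_wearable_window(nn)


def window(night="n0", start=0.0, **params):
    w = HRVWindow(night_id=night, window_start_s=start, source="wearable")
    for k, v in params.items():
        setattr(w, k, v)
    return w


class TestNightlyAverage:
    def test_plain_mean(self):
        s = nightly_average([window(start=0.0, hr_bpm=60.0), window(start=300.0, hr_bpm=70.0)])
        assert s.means["hr_bpm"] == pytest.approx(65.0)
        assert s.n_windows_used == 2

    def test_missing_values_skipped_per_parameter(self):
        wins = [window(start=0.0, hr_bpm=60.0, lf_hf=2.0),
                window(start=300.0, hr_bpm=61.0),
                window(start=600.0, hr_bpm=62.0, lf_hf=4.0)]
        s = nightly_average(wins)
        assert s.means["lf_hf"] == pytest.approx(3.0)
        assert s.n_per_parameter["lf_hf"] == 2
        assert s.n_per_parameter["hr_bpm"] == 3

    def test_identical_windows_average_to_window_value(self):
        wins = [window(start=300.0 * k, hr_bpm=58.5, rmssd_ms=42.0) for k in range(5)]
        s = nightly_average(wins)
        assert s.means["hr_bpm"] == 58.5 and s.means["rmssd_ms"] == 42.0

    def test_all_gated_night_errors(self):
        wins = [window(start=0.0)]
        wins[0].gated_out = True
        with pytest.raises(ValueError, match="no usable"):
            nightly_average(wins)
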