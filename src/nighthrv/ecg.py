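"""Single-lead ECG processing: filtering, windowing, R-peak detection, window validation.

The detection scheme is a two-round thresholding detector. Round 1 keeps every
local maximum above the window's mean amplitude (a deliberately permissive
superset containing R peaks plus P/T/noise peaks). Round 2 re-thresholds at a
fraction of the mean round-1 peak amplitude, enforces a physiologic refractory
period, and searches long inter-peak gaps at a lowered threshold to recover
missed beats. Window validation then rejects windows whose rhythm falls outside
the normal nocturnal range (50-200 bpm; RR in 300-1200 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

__all__ = [
    "WaveformRecord",
    "PeakSeries",
    "WindowQuality",
    "bandpass",
    "segment_windows",
    "detect_peaks_round1",
    "detect_peaks_round2",
    "validate_window",
]

#: Normal heart-beat frequency range (bpm) used throughout validation.
HR_RANGE_BPM = (50.0, 200.0)
#: The same range expressed as RR-interval bounds in milliseconds.
RR_RANGE_MS = (60000.0 / HR_RANGE_BPM[1], 60000.0 / HR_RANGE_BPM[0])


@dataclass(frozen=True)
class WaveformRecord:
    """Uniformly sampled single-channel waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitudes, arbitrary units.
    sampling_rate_hz : float
        Sampling rate, must be positive.
    start_time_s : float
        Time of the first sample relative to the recording start.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if np.isnan(samples).any():
            raise ValueError("samples contain NaN; encode signal loss as flat gaps instead")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class PeakSeries:
    """Detected peaks inside one window.

    ``indices`` are sample indices into the window's record (strictly
    increasing); times/amplitudes are derived at construction. ``n_removed`` and
    ``n_added`` are filled by round-2 detection (peaks dropped from round 1 and
    re-admitted by search-back, respectively).
    """

    indices: np.ndarray
    times_s: np.ndarray
    amplitudes: np.ndarray
    window_id: float = 0.0
    n_removed: int = 0
    n_added: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @classmethod
    def from_indices(cls, record: WaveformRecord, indices: np.ndarray, **kw) -> "PeakSeries":
        indices = np.asarray(indices, dtype=int)
        return cls(
            indices=indices,
            times_s=record.start_time_s + indices / record.sampling_rate_hz,
            amplitudes=record.samples[indices] if indices.size else np.empty(0),
            window_id=record.start_time_s,
            **kw,
        )


@dataclass(frozen=True)
class WindowQuality:
    """Validity verdict for one 5-minute window."""

    window_id: float
    n_peaks: int
    n_removed: int
    n_added: int
    fraction_rr_in_range: float
    mean_hr_bpm: float
    is_valid: bool
    reject_reason: str = ""
    amplitude_cv: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_rr_in_range <= 1.0:
            raise ValueError("fraction_rr_in_range must lie in [0, 1]")
        if self.is_valid and self.reject_reason:
            raise ValueError("valid windows carry no reject reason")


def bandpass(
    record: WaveformRecord,
    low_hz: float = 0.5,
    high_hz: float = 100.0,
    order: int = 4,
) -> WaveformRecord:
    """Zero-phase Butterworth band-pass filter.

    Forward-backward (``sosfiltfilt``) application avoids any phase shift of
    the R peak; the effective attenuation is therefore twice the one-pass
    filter order. Length and sampling metadata are preserved.
    """
    nyq = record.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high cutoff {high_hz} Hz is not below the Nyquist frequency {nyq} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=record.sampling_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, record.samples)
    return replace(record, samples=filtered)


def segment_windows(record: WaveformRecord, window_s: float = 300.0) -> list[WaveformRecord]:
    """Split a record into consecutive non-overlapping windows.

    Windows are aligned to the record start; a trailing partial window is
    dropped. A record shorter than one window yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_per = int(round(window_s * record.sampling_rate_hz))
    n_windows = record.n_samples // n_per
    out = []
    for k in range(n_windows):
        out.append(
            WaveformRecord(
                samples=record.samples[k * n_per : (k + 1) * n_per],
                sampling_rate_hz=record.sampling_rate_hz,
                start_time_s=record.start_time_s + k * window_s,
            )
        )
    return out


def detect_peaks_round1(window: WaveformRecord) -> PeakSeries:
    """First-round detection: all strict local maxima above the window mean.

    Intentionally permissive: the result is a superset containing the true R
    peaks together with P/T-wave and noise peaks; round 2 prunes it. A constant
    window has no local maxima and yields an empty series.
    """
    x = window.samples
    peaks, _ = signal.find_peaks(x, height=float(x.mean()))
    return PeakSeries.from_indices(window, peaks)


def _refractory_pass(idx: np.ndarray, amps: np.ndarray, min_gap: float, fs: float) -> np.ndarray:
    """Greedy scan keeping the larger of any two peaks closer than ``min_gap`` s.

    Ties keep the earlier peak. Returns positions (into idx) kept.
    """
    keep: list[int] = []
    min_samples = min_gap * fs
    for k in range(idx.size):
        if not keep:
            keep.append(k)
            continue
        last = keep[-1]
        if idx[k] - idx[last] < min_samples:
            if amps[k] > amps[last]:  # tie -> keep earlier
                keep[-1] = k
        else:
            keep.append(k)
    return np.asarray(keep, dtype=int)


def detect_peaks_round2(
    window: WaveformRecord,
    round1: PeakSeries,
    theta: float = 0.5,
    theta_prime: float = 0.3,
    refractory_s: float = 60.0 / HR_RANGE_BPM[1],
    search_back_s: float = 60.0 / HR_RANGE_BPM[0],
) -> PeakSeries:
    """Second-round detection: re-threshold, refractory pruning, search-back.

    The reference amplitude is the mean of the round-1 peak amplitudes. Steps,
    repeated until a fixed point:

    1. drop peaks below ``theta`` x reference (P/T/noise rejection);
    2. of any two retained peaks closer than ``refractory_s`` (300 ms at the
       200-bpm limit), keep the larger (tie: the earlier);
    3. for any retained inter-peak gap longer than ``search_back_s`` (1200 ms at
       the 50-bpm limit), re-admit the largest round-1 peak inside the gap that
       exceeds ``theta_prime`` x reference and sits at least one refractory
       period from both gap edges.

    Finally, peaks closer than one refractory period to either window edge are
    discarded: they cannot be refractory-checked against the neighbouring
    window, and every orphan P/T false positive created by cutting a beat
    complex at the boundary falls inside that margin.

    The output is always a subset of the round-1 peaks; no new positions are
    fabricated. Running the procedure on its own output is a no-op.
    """
    if len(round1) == 0:
        return PeakSeries.from_indices(window, np.empty(0, dtype=int))
    fs = window.sampling_rate_hz
    ref_amp = float(round1.amplitudes.mean())
    all_idx = round1.indices
    all_amp = round1.amplitudes

    mask = all_amp >= theta * ref_amp
    current = all_idx[mask]
    cur_amp = all_amp[mask]

    n_added = 0
    for _ in range(1000):  # fixed-point iteration; bounded defensively
        kept = _refractory_pass(current, cur_amp, refractory_s, fs)
        current, cur_amp = current[kept], cur_amp[kept]

        admitted = []
        gap_samples = search_back_s * fs
        guard = refractory_s * fs
        for a, b in zip(current[:-1], current[1:]):
            if b - a <= gap_samples:
                continue
            inside = (all_idx > a + guard) & (all_idx < b - guard)
            cand_amp = np.where(inside, all_amp, -np.inf)
            if not inside.any():
                continue
            best = int(np.argmax(cand_amp))  # argmax ties -> earliest
            if all_amp[best] >= theta_prime * ref_amp:
                admitted.append(best)
        if not admitted:
            break
        n_added += len(admitted)
        current = np.sort(np.concatenate([current, all_idx[admitted]]))
        lookup = {int(i): float(v) for i, v in zip(all_idx, all_amp)}
        cur_amp = np.array([lookup[int(i)] for i in current])

    # edge guard: a peak within one refractory period of the window boundary
    # cannot be validated against the neighbouring window's beats
    margin = refractory_s * fs
    edge_ok = (current >= margin) & (current <= window.n_samples - 1 - margin)
    current = current[edge_ok]

    # output is a subset of round 1, so removals are the count difference
    return PeakSeries.from_indices(
        window, current, n_removed=len(round1) - current.size, n_added=n_added
    )


def validate_window(
    window: WaveformRecord,
    peaks: PeakSeries,
    rr_range_ms: tuple[float, float] = RR_RANGE_MS,
    hr_range_bpm: tuple[float, float] = HR_RANGE_BPM,
    min_valid_fraction: float = 0.8,
    max_amplitude_cv: float = 0.25,
    min_kurtosis: float = 5.0,
) -> WindowQuality:
    """Quality gate for one window, based on normal HR / RR ranges plus a
    signal-quality check on peak-amplitude consistency.

    Criteria, in order:

    * at least two peaks;
    * window mean HR in ``hr_range_bpm``. Two estimates must both pass: the
      gross beat rate (peak count over window duration — this catches
      electrode-dropout windows where the few surviving beats look normal) and
      60000/mean of the in-range RR intervals;
    * sample kurtosis of the window at least ``min_kurtosis`` (the classic
      kSQI: a clean ECG is dominated by narrow QRS spikes and is strongly
      leptokurtic, whereas noise-dominated segments sit near the Gaussian value
      of 3; skipped for constant windows where kurtosis is undefined);
    * peak-amplitude coefficient of variation at most ``max_amplitude_cv``:
      genuine R peaks have consistent amplitudes, while high-energy noise
      bursts yield erratic ones that the refractory rule otherwise launders
      into plausible tachycardic RR intervals (skipped when amplitudes are not
      positive on average, e.g. annotation-only peak series);
    * fraction of RR intervals inside ``rr_range_ms`` at least
      ``min_valid_fraction``.
    """
    if len(peaks) < 2:
        return WindowQuality(
            window_id=peaks.window_id if len(peaks) else window.start_time_s,
            n_peaks=len(peaks),
            n_removed=peaks.n_removed,
            n_added=peaks.n_added,
            fraction_rr_in_range=0.0,
            mean_hr_bpm=float("nan"),
            is_valid=False,
            reject_reason="insufficient peaks",
        )
    rr_ms = np.diff(peaks.times_s) * 1000.0
    in_range = (rr_ms >= rr_range_ms[0]) & (rr_ms <= rr_range_ms[1])
    fraction = float(in_range.mean())
    count_hr = len(peaks) * 60.0 / window.duration_s
    rr_hr = 60000.0 / float(rr_ms[in_range].mean()) if in_range.any() else float("nan")
    mean_amp = float(peaks.amplitudes.mean())
    amp_cv = float(peaks.amplitudes.std() / mean_amp) if mean_amp > 0 else float("nan")

    kurt = float(stats.kurtosis(window.samples, fisher=False)) if window.samples.std() > 0 else float("nan")

    lo, hi = hr_range_bpm
    reason = ""
    if not in_range.any() or not (lo <= count_hr <= hi and lo <= rr_hr <= hi):
        reason = "HR out of range"
    elif np.isfinite(kurt) and kurt < min_kurtosis:
        reason = "low signal quality (kurtosis)"
    elif mean_amp > 0 and amp_cv > max_amplitude_cv:
        reason = "inconsistent peak amplitudes"
    elif fraction < min_valid_fraction:
        reason = "too many out-of-range RR intervals"
    return WindowQuality(
        window_id=peaks.window_id,
        n_peaks=len(peaks),
        n_removed=peaks.n_removed,
        n_added=peaks.n_added,
        fraction_rr_in_range=fraction,
        mean_hr_bpm=count_hr,
        is_valid=reason == "",
        reject_reason=reason,
        amplitude_cv=amp_cv,
    )
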