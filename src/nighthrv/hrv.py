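"""Heart-rate-variability parameters from normal-to-normal (NN) interval series.

Eight parameters are computed per 5-minute window: HR, RMSSD, AVNN, SDNN,
pNN50 (time domain) and LF, HF, LF:HF (frequency domain, Lomb-Scargle on the
unevenly sampled tachogram). Definitions:

* AVNN: mean NN interval (ms); HR = 60000 / AVNN (bpm).
* SDNN: sample standard deviation (n-1 denominator) of NN intervals (ms).
* RMSSD: root mean square of successive differences between *adjacent* NN
  intervals (ms) — an excluded interval breaks adjacency on both sides.
* pNN50: number of adjacent pairs differing by more than 50 ms divided by the
  total number of NN intervals, reported as a proportion in [0, 1]. (Many
  references divide by the number of pairs; this package divides by the
  interval count.)
* LF, HF: spectral power (ms^2) of the NN series in 0.04-0.15 Hz and
  0.15-0.4 Hz; the 0.15 Hz boundary belongs to HF only. LF:HF is their ratio,
  undefined (NaN) when HF is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "NNSeries",
    "HRVWindow",
    "NightSummary",
    "PARAMETERS",
    "nn_from_peaks",
    "time_domain",
    "frequency_domain",
    "gate_wearable_window",
    "nightly_average",
]

#: Canonical parameter (column) names, in reporting order.
PARAMETERS = ("hr_bpm", "rmssd_ms", "avnn_ms", "sdnn_ms", "pnn50", "lf_ms2", "hf_ms2", "lf_hf")

LF_BAND_HZ = (0.04, 0.15)  # [low, high): 0.15 counted in HF
HF_BAND_HZ = (0.15, 0.4)  # [low, high]
PNN_THRESHOLD_MS = 50.0
#: Per-interval plausibility range (ms), the 50-200 bpm normal band.
NN_RANGE_MS = (300.0, 1200.0)
#: Frequency-domain floor: minimum NN count and minimum spanned time.
FREQ_MIN_NN = 30
FREQ_MIN_SPAN_S = 120.0


@dataclass(frozen=True)
class NNSeries:
    """Ordered beat times with derived NN intervals and validity flags.

    ``beat_times_s`` has one more element than ``nn_ms``; ``nn_ms[k]`` is the
    interval ending at ``beat_times_s[k+1]``. ``valid[k]`` is False for
    intervals excluded from the normal set (artifacts, out-of-range, device
    invalid flags).
    """

    beat_times_s: np.ndarray
    nn_ms: np.ndarray
    valid: np.ndarray
    source: str = "ecg"

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        nn = np.asarray(self.nn_ms, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "beat_times_s", t)
        object.__setattr__(self, "nn_ms", nn)
        object.__setattr__(self, "valid", v)
        if t.size != nn.size + 1:
            raise ValueError("beat_times_s must have exactly one more element than nn_ms")
        if nn.size != v.size:
            raise ValueError("valid flags must align with nn_ms")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(nn <= 0):
            raise ValueError("NN intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times_s: np.ndarray, valid=None, source: str = "ecg") -> "NNSeries":
        t = np.asarray(beat_times_s, dtype=float)
        nn = np.diff(t) * 1000.0
        if valid is None:
            valid = np.ones(nn.size, dtype=bool)
        return cls(beat_times_s=t, nn_ms=nn, valid=valid, source=source)

    def __len__(self) -> int:
        return int(self.nn_ms.size)

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self) else 0.0

    @property
    def end_times_s(self) -> np.ndarray:
        """Time of each interval's closing beat."""
        return self.beat_times_s[1:]

    def slice_window(self, start_s: float, stop_s: float) -> "NNSeries":
        """Sub-series of intervals lying entirely inside [start_s, stop_s).

        Both endpoints must fall in the window — the same membership a peak
        detector restricted to the window's samples can observe.
        """
        m = (self.beat_times_s[:-1] >= start_s) & (self.end_times_s < stop_s)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            return NNSeries(np.array([start_s]), np.empty(0), np.empty(0, bool), self.source)
        lo, hi = idx[0], idx[-1] + 1
        return NNSeries(
            beat_times_s=self.beat_times_s[lo : hi + 1],
            nn_ms=self.nn_ms[lo:hi],
            valid=self.valid[lo:hi],
            source=self.source,
        )


@dataclass
class HRVWindow:
    """One window's parameter set plus validity metadata.

    Missing parameters (e.g. frequency domain on too-short data) are NaN;
    gated-out windows carry no values at all.
    """

    night_id: str
    window_start_s: float
    source: str
    hr_bpm: float = math.nan
    rmssd_ms: float = math.nan
    avnn_ms: float = math.nan
    sdnn_ms: float = math.nan
    pnn50: float = math.nan
    lf_ms2: float = math.nan
    hf_ms2: float = math.nan
    lf_hf: float = math.nan
    n_nn: int = 0
    valid_fraction: float = math.nan
    gated_out: bool = False

    def value(self, parameter: str) -> float:
        return getattr(self, parameter)


@dataclass
class NightSummary:
    """Per-night unweighted means over non-gated windows, per parameter."""

    night_id: str
    source: str
    means: dict = field(default_factory=dict)
    n_windows_used: int = 0
    n_per_parameter: dict = field(default_factory=dict)

    def value(self, parameter: str) -> float:
        return self.means.get(parameter, math.nan)


def nn_from_peaks(peaks, quality, nn_range_ms: tuple[float, float] = NN_RANGE_MS) -> NNSeries:
    """NN series from a validated window's detected peaks.

    Successive peak-time differences become intervals; intervals outside
    ``nn_range_ms`` are flagged invalid and break adjacency for
    successive-difference statistics.
    """
    if not quality.is_valid:
        raise ValueError(f"window {quality.window_id} failed validation: {quality.reject_reason}")
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to form an interval")
    t = np.asarray(peaks.times_s, dtype=float)
    nn = np.diff(t) * 1000.0
    valid = (nn >= nn_range_ms[0]) & (nn <= nn_range_ms[1])
    return NNSeries(beat_times_s=t, nn_ms=nn, valid=valid, source="ecg")


def time_domain(nn: NNSeries) -> dict[str, float]:
    """AVNN, HR, SDNN, RMSSD and pNN50 over the valid intervals of ``nn``.

    Successive-difference statistics use only pairs of *adjacent* valid
    intervals; SDNN requires at least two valid intervals (else NaN), RMSSD and
    pNN50 at least one adjacent pair (else NaN; pNN50 is 0 when pairs exist but
    none exceed the threshold).
    """
    vals = nn.nn_ms[nn.valid]
    if vals.size == 0:
        raise ValueError("empty NN set")
    avnn = float(vals.mean())
    out = {
        "avnn_ms": avnn,
        "hr_bpm": 60000.0 / avnn,
        "sdnn_ms": float(vals.std(ddof=1)) if vals.size >= 2 else math.nan,
    }
    adj = nn.valid[:-1] & nn.valid[1:]
    if adj.any():
        d = np.diff(nn.nn_ms)[adj]
        out["rmssd_ms"] = float(np.sqrt(np.mean(d**2)))
        out["pnn50"] = float((np.abs(d) > PNN_THRESHOLD_MS).sum() / vals.size)
    else:
        out["rmssd_ms"] = math.nan
        out["pnn50"] = math.nan
    return out


def _lomb_scargle_band_power(t: np.ndarray, y: np.ndarray, oversample: int = 8):
    """Band powers (LF, HF) in ms^2 from a Lomb-Scargle periodogram.

    The unnormalized periodogram P is scaled by 2T/N so that integrating the
    spectral peak of a pure sinusoid of amplitude A recovers its power A^2/2,
    and integrating white noise over the full band recovers its variance.
    """
    span = t[-1] - t[0]
    df = 1.0 / (oversample * span)
    freqs = np.arange(df, 0.5 + df, df)
    power = signal.lombscargle(t, y, 2.0 * np.pi * freqs)
    psd = power * 2.0 * span / t.size
    lf_mask = (freqs >= LF_BAND_HZ[0]) & (freqs < LF_BAND_HZ[1])
    hf_mask = (freqs >= HF_BAND_HZ[0]) & (freqs <= HF_BAND_HZ[1])
    return float(psd[lf_mask].sum() * df), float(psd[hf_mask].sum() * df)


def _welch_band_power(t: np.ndarray, y: np.ndarray, resample_hz: float = 4.0):
    """Alternative estimator: cubic-spline resampling at 4 Hz + Welch PSD."""
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    resampled = interpolate.CubicSpline(t, y)(grid)
    nperseg = min(resampled.size, int(resample_hz * 120))
    freqs, psd = signal.welch(resampled, fs=resample_hz, nperseg=nperseg, detrend="constant")
    df = freqs[1] - freqs[0]
    lf_mask = (freqs >= LF_BAND_HZ[0]) & (freqs < LF_BAND_HZ[1])
    hf_mask = (freqs >= HF_BAND_HZ[0]) & (freqs <= HF_BAND_HZ[1])
    return float(psd[lf_mask].sum() * df), float(psd[hf_mask].sum() * df)


def frequency_domain(nn: NNSeries, estimator: str = "lombscargle") -> dict[str, float]:
    """LF and HF band power (ms^2) and their ratio for one window.

    The default estimator is a Lomb-Scargle periodogram computed directly on
    the unevenly sampled valid NN intervals (abscissa: each interval's closing
    beat time), which avoids interpolation bias over gaps. ``estimator="welch"``
    selects 4-Hz cubic-spline resampling + Welch instead, for sensitivity
    analysis. LF:HF is NaN when HF is zero.
    """
    m = nn.valid
    t = nn.end_times_s[m]
    y = nn.nn_ms[m]
    if y.size < FREQ_MIN_NN or (t.size and t[-1] - t[0] < FREQ_MIN_SPAN_S):
        raise ValueError(
            f"frequency-domain analysis needs >= {FREQ_MIN_NN} NN intervals spanning >= {FREQ_MIN_SPAN_S} s"
        )
    y = y - y.mean()
    if estimator == "lombscargle":
        lf, hf = _lomb_scargle_band_power(t, y)
    elif estimator == "welch":
        lf, hf = _welch_band_power(t, y)
    else:
        raise ValueError(f"unknown spectral estimator {estimator!r}")
    return {"lf_ms2": lf, "hf_ms2": hf, "lf_hf": lf / hf if hf > 0 else math.nan}


def gate_wearable_window(nn: NNSeries, threshold: float = 0.30) -> bool:
    """Whether a wearable window has enough valid signal to be analyzed.

    Retained iff the valid fraction is at least ``threshold`` (boundary
    inclusive; the default keeps windows with exactly 30% validity).
    """
    if len(nn) == 0:
        return False
    return nn.valid_fraction >= threshold - 1e-12


def nightly_average(windows: list[HRVWindow], night_id: str | None = None) -> NightSummary:
    """Unweighted mean of each parameter over non-gated windows of one night.

    Per-parameter missingness is independent: a window with a missing LF:HF
    still contributes its HR. Raises if no usable window remains.
    """
    usable = [w for w in windows if not w.gated_out]
    if not usable:
        raise ValueError("no usable (non-gated) windows for nightly average")
    nid = night_id if night_id is not None else usable[0].night_id
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in PARAMETERS:
        vals = [w.value(p) for w in usable if not math.isnan(w.value(p))]
        counts[p] = len(vals)
        means[p] = float(np.mean(vals)) if vals else math.nan
    return NightSummary(
        night_id=nid,
        source=usable[0].source,
        means=means,
        n_windows_used=len(usable),
        n_per_parameter=counts,
    )
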