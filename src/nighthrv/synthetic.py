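"""Ground-truth-annotated synthetic inputs emulating both study channels.

Two devices are emulated for paired overnight recordings:

* a chest ECG channel: a single-lead waveform with a dominant R deflection per
  beat (Gaussian spike plus smaller P/T bumps), baseline wander, additive
  noise, optional motion-artifact bursts and electrode-dropout gaps;
* a finger-PPG ring channel: a beat-by-beat interbeat-interval (IBI) export
  with per-sample validity flags, and per-5-minute HR/HRV values modelled as
  ground truth plus a configurable additive bias and Gaussian noise per
  parameter.

Beat intervals carry sinusoidal autonomic modulation in the LF (0.04-0.15 Hz)
and HF (0.15-0.4 Hz) bands plus white beat-to-beat jitter, so every window has
known time- and frequency-domain HRV ground truth. All randomness flows from
explicit seeds in the spec dataclasses; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .ecg import WaveformRecord
from .hrv import PARAMETERS, NNSeries, frequency_domain, time_domain

__all__ = [
    "TachogramSpec",
    "EcgSpec",
    "DeviceErrorSpec",
    "GroundTruth",
    "NightData",
    "StudyBundle",
    "generate_tachogram",
    "synthesize_ecg",
    "simulate_device_pair",
]

WINDOW_S = 300.0
#: Time of the first beat. A recording never starts exactly on an R peak, and a
#: deflection at sample 0 is not a detectable local maximum, so the rhythm
#: begins a fixed short pad after recording start.
START_PAD_S = 0.3


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class TachogramSpec:
    """Beat-interval model: mean NN plus LF/HF sinusoids plus white jitter.

    NN_k = mean_nn_ms + lf_amp*sin(2*pi*lf_freq*t_k) + hf_amp*sin(2*pi*hf_freq*t_k) + eps_k,
    with t_k the cumulative beat time and eps_k ~ N(0, jitter_sd_ms^2).

    Defaults describe a healthy adult asleep: 60 bpm with moderate vagal (HF)
    and baroreflex-band (LF) modulation.
    """

    duration_s: float = 4800.0
    mean_nn_ms: float = 1000.0
    lf_amp_ms: float = 40.0
    lf_freq_hz: float = 0.095
    hf_amp_ms: float = 30.0
    hf_freq_hz: float = 0.25
    jitter_sd_ms: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.duration_s > 0, "duration_s", "must be positive")
        _check(300.0 <= self.mean_nn_ms <= 1200.0, "mean_nn_ms", "must lie in [300, 1200] ms (50-200 bpm)")
        _check(0.04 <= self.lf_freq_hz < 0.15, "lf_freq_hz", "must lie in [0.04, 0.15) Hz")
        _check(0.15 <= self.hf_freq_hz <= 0.4, "hf_freq_hz", "must lie in [0.15, 0.4] Hz")
        for name in ("lf_amp_ms", "hf_amp_ms", "jitter_sd_ms"):
            v = getattr(self, name)
            _check(0 <= v < self.mean_nn_ms / 2, name, "must be >= 0 and < mean_nn_ms/2")

    # closed-form targets for parameter-recovery tests -------------------
    @property
    def analytic_sdnn_ms(self) -> float:
        """SD of the NN series: sinusoid variances A^2/2 plus jitter variance."""
        return math.sqrt(self.lf_amp_ms**2 / 2 + self.hf_amp_ms**2 / 2 + self.jitter_sd_ms**2)

    @property
    def analytic_rmssd_ms(self) -> float:
        """RMS successive difference: 2 A^2 sin^2(pi f dt) per band + 2 sigma^2."""
        dt = self.mean_nn_ms / 1000.0
        s = 2 * self.jitter_sd_ms**2
        for amp, f in ((self.lf_amp_ms, self.lf_freq_hz), (self.hf_amp_ms, self.hf_freq_hz)):
            s += 2 * amp**2 * math.sin(math.pi * f * dt) ** 2
        return math.sqrt(s)

    @property
    def analytic_lf_ms2(self) -> float:
        return self.lf_amp_ms**2 / 2

    @property
    def analytic_hf_ms2(self) -> float:
        return self.hf_amp_ms**2 / 2


@dataclass(frozen=True)
class EcgSpec:
    """Waveform model placed on top of a tachogram.

    Each beat contributes a narrow positive Gaussian R spike (sd
    ``r_width_s``), a smaller P bump before and T bump after it. Baseline
    wander is a slow sinusoid; ``artifact_bursts`` are (start_s, duration_s,
    amplitude) high-energy noise segments and ``dropout_gaps`` are (start_s,
    duration_s) flat segments emulating lost electrode contact.
    """

    tachogram: TachogramSpec = field(default_factory=TachogramSpec)
    sampling_rate_hz: float = 512.0
    r_amplitude: float = 1.0
    r_width_s: float = 0.012
    p_amplitude_frac: float = 0.15
    t_amplitude_frac: float = 0.30
    baseline_wander_amp: float = 0.05
    baseline_wander_freq_hz: float = 0.33
    noise_sd: float = 0.02
    artifact_bursts: tuple = ()
    dropout_gaps: tuple = ()

    def __post_init__(self) -> None:
        _check(self.sampling_rate_hz >= 128, "sampling_rate_hz", "must be >= 128 Hz")
        _check(self.r_amplitude > 0, "r_amplitude", "must be positive")
        for name, triples in (("artifact_bursts", self.artifact_bursts), ("dropout_gaps", self.dropout_gaps)):
            for seg in triples:
                _check(
                    0 <= seg[0] and seg[0] + seg[1] <= self.tachogram.duration_s,
                    name,
                    f"segment {seg} must lie within [0, duration_s]",
                )


@dataclass(frozen=True)
class DeviceErrorSpec:
    """Additive wearable error model: value = truth + bias + N(0, sd^2).

    One (bias, sd) pair per parameter, plus the proportion of IBI samples
    flagged invalid in each window (laid down as contiguous runs, mimicking
    motion-artifact episodes). Defaults are error magnitudes representative of
    a finger-PPG ring against a chest ECG during sleep: small biases, with
    window-level noise far larger for the spectral parameters than for HR.
    """

    hr_bias: float = -0.44
    hr_sd: float = 1.2092
    rmssd_bias: float = -14.97
    rmssd_sd: float = 14.847
    avnn_bias: float = -13.39
    avnn_sd: float = 100.319
    sdnn_bias: float = -0.96
    sdnn_sd: float = 44.635
    pnn50_bias: float = 0.06
    pnn50_sd: float = 0.14796
    lf_bias: float = 23.61
    lf_sd: float = 909.44
    hf_bias: float = 30.23
    hf_sd: float = 741.91
    lf_hf_bias: float = -0.11
    lf_hf_sd: float = 1.2347
    invalid_fraction: float = 0.1
    seed: int = 0

    _FIELD_BY_PARAM = {
        "hr_bpm": "hr",
        "rmssd_ms": "rmssd",
        "avnn_ms": "avnn",
        "sdnn_ms": "sdnn",
        "pnn50": "pnn50",
        "lf_ms2": "lf",
        "hf_ms2": "hf",
        "lf_hf": "lf_hf",
    }

    def __post_init__(self) -> None:
        for p, stem in self._FIELD_BY_PARAM.items():
            _check(getattr(self, f"{stem}_sd") >= 0, f"{stem}_sd", "noise SD must be >= 0")
        _check(0 <= self.invalid_fraction <= 1, "invalid_fraction", "must lie in [0, 1]")

    def bias(self, parameter: str) -> float:
        return getattr(self, f"{self._FIELD_BY_PARAM[parameter]}_bias")

    def sd(self, parameter: str) -> float:
        return getattr(self, f"{self._FIELD_BY_PARAM[parameter]}_sd")

    @classmethod
    def zero(cls, invalid_fraction: float = 0.0, seed: int = 0) -> "DeviceErrorSpec":
        """Error-free wearable (useful for null-model pipeline checks)."""
        kw = {f"{stem}_{k}": 0.0 for stem in cls._FIELD_BY_PARAM.values() for k in ("bias", "sd")}
        return cls(invalid_fraction=invalid_fraction, seed=seed, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Exact beat times, NN series and per-window parameter truth.

    ``window_params`` has one row per complete 5-minute window with the eight
    parameters computed from the true (uncorrupted) NN series; ``in_gap`` flags
    beats that fall inside an ECG dropout gap (they are still listed).
    """

    true_beat_times_s: np.ndarray
    nn: NNSeries
    window_params: pd.DataFrame
    in_gap: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.true_beat_times_s, dtype=float)
        object.__setattr__(self, "true_beat_times_s", t)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("true beat times must be strictly increasing")


def _true_window_params(nn: NNSeries, duration_s: float) -> pd.DataFrame:
    rows = []
    for k in range(int(duration_s // WINDOW_S)):
        start = k * WINDOW_S
        sub = nn.slice_window(start, start + WINDOW_S)
        row = {"window_start_s": start}
        row.update(time_domain(sub))
        try:
            row.update(frequency_domain(sub))
        except ValueError:
            row.update({"lf_ms2": math.nan, "hf_ms2": math.nan, "lf_hf": math.nan})
        rows.append(row)
    cols = ["window_start_s", *PARAMETERS]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def generate_tachogram(spec: TachogramSpec) -> tuple[NNSeries, GroundTruth]:
    """Generate the beat-interval series and its ground truth.

    Beats accumulate from t=0: each interval is evaluated at the time of its
    opening beat, so the modulation phase advances with the (slightly
    irregular) beat clock rather than wall-clock samples. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    t = START_PAD_S
    times = [t]
    nn = []
    while t < spec.duration_s:
        v = (
            spec.mean_nn_ms
            + spec.lf_amp_ms * math.sin(2 * math.pi * spec.lf_freq_hz * t)
            + spec.hf_amp_ms * math.sin(2 * math.pi * spec.hf_freq_hz * t)
            + rng.normal(0.0, spec.jitter_sd_ms)
        )
        v = max(v, 1.0)  # degenerate-jitter guard; unreachable under the invariants
        t += v / 1000.0
        times.append(t)
        nn.append(v)
    series = NNSeries(
        beat_times_s=np.asarray(times),
        nn_ms=np.asarray(nn),
        valid=np.ones(len(nn), dtype=bool),
        source="truth",
    )
    truth = GroundTruth(
        true_beat_times_s=np.asarray(times),
        nn=series,
        window_params=_true_window_params(series, spec.duration_s),
    )
    return series, truth


def synthesize_ecg(spec: EcgSpec) -> tuple[WaveformRecord, GroundTruth]:
    """Render an ECG-like waveform from a tachogram spec.

    One Gaussian R spike of height ``r_amplitude`` per true beat, plus P/T
    bumps, baseline wander, white noise, artifact bursts and dropout gaps. The
    returned ground truth lists every beat (beats inside gaps are flagged, not
    dropped).
    """
    _, truth = generate_tachogram(spec.tachogram)
    # beats at/after the record end are not rendered and not part of the truth
    beats = truth.true_beat_times_s[truth.true_beat_times_s < spec.tachogram.duration_s]
    min_nn_s = float(np.diff(beats).min()) if beats.size >= 2 else math.inf
    template_width_s = 6 * spec.r_width_s
    if min_nn_s < template_width_s:
        raise ValueError(
            f"beats denser ({min_nn_s:.3f} s) than the R template width ({template_width_s:.3f} s)"
        )

    fs = spec.sampling_rate_hz
    n = int(round(spec.tachogram.duration_s * fs))
    x = np.zeros(n)

    def add_bump(center_s: float, amp: float, sd_s: float) -> None:
        lo = max(int((center_s - 4 * sd_s) * fs), 0)
        hi = min(int((center_s + 4 * sd_s) * fs) + 1, n)
        if lo >= hi:
            return
        tt = np.arange(lo, hi) / fs
        x[lo:hi] += amp * np.exp(-0.5 * ((tt - center_s) / sd_s) ** 2)

    for b in beats:
        add_bump(b, spec.r_amplitude, spec.r_width_s)
        if spec.p_amplitude_frac > 0:
            add_bump(b - 0.18, spec.p_amplitude_frac * spec.r_amplitude, 0.025)
        if spec.t_amplitude_frac > 0:
            add_bump(b + 0.22, spec.t_amplitude_frac * spec.r_amplitude, 0.045)

    t_samples = np.arange(n) / fs
    if spec.baseline_wander_amp:
        x += spec.baseline_wander_amp * np.sin(2 * np.pi * spec.baseline_wander_freq_hz * t_samples)
    rng = np.random.default_rng(np.random.SeedSequence([spec.tachogram.seed, 0x0EC6]))
    if spec.noise_sd:
        x += rng.normal(0.0, spec.noise_sd, n)
    for start_s, dur_s, amp in spec.artifact_bursts:
        lo, hi = int(start_s * fs), min(int((start_s + dur_s) * fs), n)
        x[lo:hi] += rng.normal(0.0, amp, hi - lo)
    in_gap = np.zeros(beats.size, dtype=bool)
    for start_s, dur_s in spec.dropout_gaps:
        lo, hi = int(start_s * fs), min(int((start_s + dur_s) * fs), n)
        x[lo:hi] = 0.0
        in_gap |= (beats >= start_s) & (beats < start_s + dur_s)

    record = WaveformRecord(samples=x, sampling_rate_hz=fs, start_time_s=0.0)
    return record, replace(truth, true_beat_times_s=beats, in_gap=in_gap)


@dataclass
class NightData:
    """In-memory bundle for one synthetic night."""

    night_id: str
    ecg: WaveformRecord
    truth: GroundTruth
    wearable_ibi: NNSeries
    wearable_windows: pd.DataFrame  # night_id, window_start_s, 8 parameters


@dataclass
class StudyBundle:
    """A full synthetic study: one NightData per night plus the generating specs."""

    nights: list[NightData]
    tachogram: TachogramSpec
    ecg_spec: EcgSpec
    error: DeviceErrorSpec
    manifest: dict = field(default_factory=dict)


def _wearable_windows(truth: GroundTruth, err: DeviceErrorSpec, rng, night_id: str) -> pd.DataFrame:
    df = truth.window_params.copy()
    for p in PARAMETERS:
        noise = rng.normal(0.0, err.sd(p), len(df)) if err.sd(p) > 0 else 0.0
        df[p] = df[p] + err.bias(p) + noise
    df.insert(0, "night_id", night_id)
    return df


def _wearable_ibi(truth: GroundTruth, err: DeviceErrorSpec, rng) -> NNSeries:
    """IBI export: true intervals with contiguous invalid runs per window."""
    nn = truth.nn
    valid = np.ones(len(nn), dtype=bool)
    ends = nn.end_times_s
    n_windows = int(math.floor(ends[-1] / WINDOW_S)) + 1 if len(nn) else 0
    for k in range(n_windows):
        in_win = np.flatnonzero((ends >= k * WINDOW_S) & (ends < (k + 1) * WINDOW_S))
        n_invalid = int(round(err.invalid_fraction * in_win.size))
        if n_invalid == 0:
            continue
        start = int(rng.integers(0, in_win.size - n_invalid + 1))
        valid[in_win[start : start + n_invalid]] = False
    return NNSeries(beat_times_s=nn.beat_times_s, nn_ms=nn.nn_ms, valid=valid, source="wearable")


def simulate_device_pair(
    tacho: TachogramSpec,
    ecg: EcgSpec,
    err: DeviceErrorSpec,
    n_nights: int,
    out_dir: str | Path | None = None,
    night_mean_nn_sd_ms: float = 70.0,
    amp_jitter_rel: float = 0.2,
) -> StudyBundle:
    """Simulate a paired overnight study of ``n_nights`` participants.

    Each night redraws the participant's mean NN (SD ``night_mean_nn_sd_ms``)
    and rescales the modulation amplitudes (lognormal, relative SD
    ``amp_jitter_rel``) so that between-participant spread exists — without it
    the between-device correlation of e.g. HR would be meaningless. Per night
    this produces an ECG waveform, a wearable IBI series with validity flags,
    and the wearable per-window parameter table (truth + bias + noise).

    If ``out_dir`` is given, the ECG / IBI / wearable-window files and a YAML
    manifest are also written in the package's delimited-text formats.
    """
    if n_nights < 1:
        raise ValueError("n_nights must be >= 1")
    master = np.random.SeedSequence([int(tacho.seed), int(err.seed), 0x9A1C])
    night_seeds = master.spawn(n_nights)
    nights: list[NightData] = []
    manifest: dict = {"n_nights": n_nights, "nights": []}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i, ss in enumerate(night_seeds):
        night_id = f"night{i:03d}"
        rng = np.random.default_rng(ss)
        tacho_seed = int(rng.integers(0, 2**31 - 1))
        mean_nn = float(np.clip(rng.normal(tacho.mean_nn_ms, night_mean_nn_sd_ms), 350.0, 1150.0))
        scale = float(rng.lognormal(0.0, amp_jitter_rel)) if amp_jitter_rel > 0 else 1.0
        limit = mean_nn / 2 * 0.98
        night_tacho = replace(
            tacho,
            mean_nn_ms=mean_nn,
            lf_amp_ms=min(tacho.lf_amp_ms * scale, limit),
            hf_amp_ms=min(tacho.hf_amp_ms * scale, limit),
            seed=tacho_seed,
        )
        night_ecg = replace(ecg, tachogram=night_tacho)
        waveform, truth = synthesize_ecg(night_ecg)
        ibi = _wearable_ibi(truth, err, rng)
        windows = _wearable_windows(truth, err, rng, night_id)
        nights.append(NightData(night_id, waveform, truth, ibi, windows))

        entry = {"night_id": night_id, "seed": tacho_seed, "mean_nn_ms": round(mean_nn, 6)}
        if out_path is not None:
            ecg_file = out_path / f"{night_id}_ecg.csv"
            ibi_file = out_path / f"{night_id}_ibi.csv"
            win_file = out_path / f"{night_id}_wearable_windows.csv"
            nio.write_ecg_text(ecg_file, waveform)
            nio.write_ibi_text(ibi_file, ibi)
            nio.write_table(win_file, windows)
            entry.update(
                ecg_file=ecg_file.name, ibi_file=ibi_file.name, wearable_windows_file=win_file.name
            )
        manifest["nights"].append(entry)

    if out_path is not None:
        nio.write_manifest(out_path / "manifest.yaml", manifest)
    return StudyBundle(nights=nights, tachogram=tacho, ecg_spec=ecg, error=err, manifest=manifest)
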