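"""End-to-end study orchestration.

``run_study`` takes a :class:`StudyConfig`, obtains paired nights (simulated,
or ingested from a manifest of delimited-text files), runs the ECG chain
(filter -> 5-minute windows -> two-round peak detection -> validity filter ->
HRV), applies the wearable validity gate, pairs the two channels per window
and per night, and emits agreement tables, an exclusion report and a
provenance record. Outputs are deterministic for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as nio
from .agreement import AgreementReport, agreement_table, bland_altman_plot, compute_agreement, pair_windows, scatter_plot
from .ecg import bandpass, detect_peaks_round1, detect_peaks_round2, segment_windows, validate_window
from .hrv import PARAMETERS, HRVWindow, NightSummary, frequency_domain, gate_wearable_window, nightly_average, nn_from_peaks, time_domain
from .synthetic import DeviceErrorSpec, EcgSpec, TachogramSpec, simulate_device_pair

__all__ = ["StudyConfig", "StudyResult", "run_study", "exclusion_report"]

log = logging.getLogger("nighthrv")

WINDOW_S = 300.0


@dataclass(frozen=True)
class StudyConfig:
    """Every tunable of the study in one serializable object."""

    # synthetic study design (ignored when a manifest is given)
    tachogram: TachogramSpec = field(default_factory=TachogramSpec)
    ecg: EcgSpec = field(default_factory=EcgSpec)
    device_error: DeviceErrorSpec = field(default_factory=DeviceErrorSpec)
    n_nights: int = 35
    night_mean_nn_sd_ms: float = 70.0
    amp_jitter_rel: float = 0.2
    manifest: str | None = None
    # ECG filter
    filter_low_hz: float = 0.5
    filter_high_hz: float = 100.0
    filter_order: int = 4
    # two-round detector
    theta: float = 0.5
    theta_prime: float = 0.3
    refractory_s: float = 0.3
    search_back_s: float = 1.2
    # validity filtering
    rr_range_ms: tuple[float, float] = (300.0, 1200.0)
    hr_range_bpm: tuple[float, float] = (50.0, 200.0)
    min_valid_rr_fraction: float = 0.8
    max_peak_amplitude_cv: float = 0.25
    wearable_gate: float = 0.30
    # spectral estimator: "lombscargle" or "welch"
    spectral_estimator: str = "lombscargle"
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        # the ECG spec always rides on the study tachogram
        if self.ecg.tachogram != self.tachogram:
            object.__setattr__(self, "ecg", replace(self.ecg, tachogram=self.tachogram))
        if not 0 < self.theta_prime <= self.theta <= 1:
            raise ValueError("need 0 < theta_prime <= theta <= 1")
        if not 0 <= self.wearable_gate <= 1:
            raise ValueError("wearable_gate must lie in [0, 1]")
        if not 0 <= self.min_valid_rr_fraction <= 1:
            raise ValueError("min_valid_rr_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ecg"].pop("tachogram", None)  # the ECG spec inherits the study tachogram
        d["rr_range_ms"] = list(d["rr_range_ms"])
        d["hr_range_bpm"] = list(d["hr_range_bpm"])
        d["ecg"]["artifact_bursts"] = [list(b) for b in self.ecg.artifact_bursts]
        d["ecg"]["dropout_gaps"] = [list(g) for g in self.ecg.dropout_gaps]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        tacho = TachogramSpec(**d.pop("tachogram", {}))
        ecg_kw = dict(d.pop("ecg", {}))
        ecg_kw.pop("tachogram", None)
        ecg_kw["artifact_bursts"] = tuple(tuple(b) for b in ecg_kw.get("artifact_bursts", ()))
        ecg_kw["dropout_gaps"] = tuple(tuple(g) for g in ecg_kw.get("dropout_gaps", ()))
        err = DeviceErrorSpec(**d.pop("device_error", {}))
        for key in ("rr_range_ms", "hr_range_bpm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(tachogram=tacho, ecg=EcgSpec(tachogram=tacho, **ecg_kw), device_error=err, **d)

    def to_yaml(self, path: str | Path) -> None:
        nio.write_manifest(path, self.to_dict())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(nio.read_manifest(path))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StudyResult:
    """Everything a study run produces, in memory."""

    config: StudyConfig
    windows: list[HRVWindow]  # both channels, including gated/absent markers
    nights: list[NightSummary]
    agreement_window: pd.DataFrame
    agreement_night: pd.DataFrame
    exclusions: pd.DataFrame  # unit_id, night_id, channel, stage, reason
    n_total_windows: int = 0

    def channel_windows(self, source: str) -> list[HRVWindow]:
        return [w for w in self.windows if w.source == source]

    def channel_nights(self, source: str) -> list[NightSummary]:
        return [n for n in self.nights if n.source == source]


def _ecg_channel(night_id, waveform, config: StudyConfig, windows_out, exclusions):
    """Filter, segment, detect and validate one night's ECG; append HRVWindows."""
    filtered = bandpass(waveform, config.filter_low_hz, config.filter_high_hz, config.filter_order)
    for win in segment_windows(filtered, WINDOW_S):
        wid = win.start_time_s
        round1 = detect_peaks_round1(win)
        if len(round1) == 0:
            exclusions.append((f"{night_id}@{wid:g}", night_id, "ecg", "peak detection", "no candidate peaks"))
            continue
        peaks = detect_peaks_round2(
            win, round1, theta=config.theta, theta_prime=config.theta_prime,
            refractory_s=config.refractory_s, search_back_s=config.search_back_s,
        )
        quality = validate_window(
            win, peaks, rr_range_ms=config.rr_range_ms,
            hr_range_bpm=config.hr_range_bpm, min_valid_fraction=config.min_valid_rr_fraction,
            max_amplitude_cv=config.max_peak_amplitude_cv,
        )
        if not quality.is_valid:
            log.warning("night %s window %g rejected: %s", night_id, wid, quality.reject_reason)
            exclusions.append((f"{night_id}@{wid:g}", night_id, "ecg", "window validation", quality.reject_reason))
            continue
        nn = nn_from_peaks(peaks, quality, nn_range_ms=config.rr_range_ms)
        row = HRVWindow(night_id=night_id, window_start_s=wid, source="ecg",
                        n_nn=len(nn), valid_fraction=nn.valid_fraction)
        for k, v in time_domain(nn).items():
            setattr(row, k, v)
        try:
            for k, v in frequency_domain(nn, estimator=config.spectral_estimator).items():
                setattr(row, k, v)
        except ValueError as exc:
            log.warning("night %s window %g: frequency domain skipped (%s)", night_id, wid, exc)
        windows_out.append(row)


def _wearable_channel(night_id, ibi, window_table, config: StudyConfig, windows_out, exclusions):
    """Gate each wearable window on IBI validity; carry the exported parameters."""
    for _, rec in window_table.iterrows():
        wid = float(rec["window_start_s"])
        sub = ibi.slice_window(wid, wid + WINDOW_S)
        if len(sub) == 0 or not gate_wearable_window(sub, threshold=config.wearable_gate):
            frac = sub.valid_fraction if len(sub) else 0.0
            log.warning("night %s window %g gated out (valid fraction %.2f)", night_id, wid, frac)
            exclusions.append((f"{night_id}@{wid:g}", night_id, "wearable", "validity gate",
                               f"valid fraction {frac:.2f} below {config.wearable_gate:.2f}"))
            windows_out.append(HRVWindow(night_id=night_id, window_start_s=wid, source="wearable",
                                         valid_fraction=frac, gated_out=True))
            continue
        row = HRVWindow(night_id=night_id, window_start_s=wid, source="wearable",
                        n_nn=len(sub), valid_fraction=sub.valid_fraction)
        for p in PARAMETERS:
            setattr(row, p, float(rec[p]))
        windows_out.append(row)


def _load_manifest_nights(config: StudyConfig):
    manifest = nio.read_manifest(config.manifest)
    base = Path(config.manifest).parent
    for entry in manifest["nights"]:
        yield (
            entry["night_id"],
            nio.read_ecg_text(base / entry["ecg_file"]),
            nio.read_ibi_text(base / entry["ibi_file"]),
            nio.read_table(base / entry["wearable_windows_file"]),
        )


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Run the full paired study and (optionally) write its report bundle."""
    if config.manifest is not None:
        night_iter = list(_load_manifest_nights(config))
    else:
        tacho = replace(config.tachogram, seed=config.seed)
        err = replace(config.device_error, seed=config.seed)
        bundle = simulate_device_pair(
            tacho, replace(config.ecg, tachogram=tacho), err, config.n_nights,
            night_mean_nn_sd_ms=config.night_mean_nn_sd_ms, amp_jitter_rel=config.amp_jitter_rel,
        )
        night_iter = [(n.night_id, n.ecg, n.wearable_ibi, n.wearable_windows) for n in bundle.nights]

    windows: list[HRVWindow] = []
    exclusions: list[tuple] = []
    nights: list[NightSummary] = []
    n_total = 0
    for night_id, waveform, ibi, wtable in night_iter:
        n_total += int(waveform.duration_s // WINDOW_S) + len(wtable)
        _ecg_channel(night_id, waveform, config, windows, exclusions)
        _wearable_channel(night_id, ibi, wtable, config, windows, exclusions)
        for source in ("ecg", "wearable"):
            night_wins = [w for w in windows if w.night_id == night_id and w.source == source]
            try:
                nights.append(nightly_average(night_wins, night_id=night_id))
            except ValueError:
                log.warning("night %s: no usable %s windows, night excluded", night_id, source)
                exclusions.append((night_id, night_id, source, "nightly average", "no usable windows"))

    excl_df = pd.DataFrame(exclusions, columns=["unit_id", "night_id", "channel", "stage", "reason"])

    def agreement_frame(granularity: str) -> pd.DataFrame:
        reports: list[AgreementReport] = []
        for p in PARAMETERS:
            if granularity == "window":
                w = [x for x in windows if x.source == "wearable"]
                r = [x for x in windows if x.source == "ecg"]
            else:
                w = [x for x in nights if x.source == "wearable"]
                r = [x for x in nights if x.source == "ecg"]
            try:
                reports.append(compute_agreement(pair_windows(w, r, p)))
            except ValueError as exc:
                log.warning("%s-level agreement skipped for %s: %s", granularity, p, exc)
        return agreement_table([rep for rep in reports])

    result = StudyResult(
        config=config,
        windows=windows,
        nights=nights,
        agreement_window=agreement_frame("window"),
        agreement_night=agreement_frame("night"),
        exclusions=excl_df,
        n_total_windows=n_total,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _windows_frame(windows: list[HRVWindow]) -> pd.DataFrame:
    cols = ["night_id", "window_start_s", "source", *PARAMETERS, "n_nn", "valid_fraction", "gated_out"]
    return pd.DataFrame([{c: getattr(w, c) for c in cols} for w in windows], columns=cols)


def _nights_frame(nights: list[NightSummary]) -> pd.DataFrame:
    rows = []
    for n in nights:
        row = {"night_id": n.night_id, "source": n.source, "n_windows_used": n.n_windows_used}
        row.update({p: n.means.get(p, math.nan) for p in PARAMETERS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["night_id", "source", "n_windows_used", *PARAMETERS])


def write_outputs(result: StudyResult, out_dir: str | Path) -> None:
    """Write the study report bundle as delimited text (+ optional plots)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": result.config.config_hash, "nighthrv_version": __version__}
    nio.write_table(out / "windows.csv", _windows_frame(result.windows), header)
    nio.write_table(out / "nights.csv", _nights_frame(result.nights), header)
    nio.write_table(out / "agreement_windows.csv", result.agreement_window, header)
    nio.write_table(out / "agreement_nights.csv", result.agreement_night, header)
    nio.write_table(out / "exclusions.csv", result.exclusions, header)
    nio.write_manifest(out / "provenance.yaml", {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash,
        "nighthrv_version": __version__,
        "n_total_windows": result.n_total_windows,
        "n_exclusions": int(len(result.exclusions)),
    })
    if result.config.plots:
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        for granularity in ("window", "night"):
            items_w = result.channel_windows("wearable") if granularity == "window" else result.channel_nights("wearable")
            items_r = result.channel_windows("ecg") if granularity == "window" else result.channel_nights("ecg")
            for p in PARAMETERS:
                try:
                    pairs = pair_windows(items_w, items_r, p)
                    rep = compute_agreement(pairs)
                except ValueError:
                    continue
                scatter_plot(pairs, rep, plot_dir / f"{granularity}_{p}_scatter.png")
                bland_altman_plot(pairs, rep, plot_dir / f"{granularity}_{p}_bland_altman.png")


def exclusion_report(result: StudyResult) -> pd.DataFrame:
    """One row per excluded unit (stage + reason); counts reconcile with totals."""
    return result.exclusions.copy()
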