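"""Delimited-text formats for waveforms, IBI exports, tables and manifests.

All files are plain text. The ECG file is two-column CSV (time_s, amplitude)
with ``# key=value`` header lines carrying the sampling rate and start time;
the IBI file is three-column CSV (beat_time_s, nn_ms, valid) emulating a
wearable cloud export. Tables are CSV with an optional ``# key=value`` comment
header (used for config-hash provenance); manifests are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import WaveformRecord
from .hrv import NNSeries

__all__ = [
    "write_ecg_text",
    "read_ecg_text",
    "write_ibi_text",
    "read_ibi_text",
    "write_table",
    "read_table",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.10g"


def write_ecg_text(path: str | Path, record: WaveformRecord) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# sampling_rate_hz={record.sampling_rate_hz:.10g}\n")
        fh.write(f"# start_time_s={record.start_time_s:.10g}\n")
        fh.write("time_s,amplitude\n")
        np.savetxt(fh, np.column_stack([record.times_s, record.samples]), fmt=_FLOAT_FMT, delimiter=",")


def _read_header(path: Path) -> tuple[dict, int]:
    meta: dict[str, float] = {}
    n = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = float(value)
    return meta, n

def read_ecg_text(path: str | Path) -> WaveformRecord:
    path = Path(path)
    meta, n_header = _read_header(path)
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# sampling_rate_hz=' header")
    df = pd.read_csv(path, skiprows=n_header)
    return WaveformRecord(
        samples=df["amplitude"].to_numpy(),
        sampling_rate_hz=meta["sampling_rate_hz"],
        start_time_s=meta.get("start_time_s", 0.0),
    )


def write_ibi_text(path: str | Path, nn: NNSeries) -> None:
    """Beat-by-beat export: one row per interval, keyed by its closing beat."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# first_beat_time_s={nn.beat_times_s[0]:.10g}\n")
        fh.write("beat_time_s,nn_ms,valid\n")
        rows = np.column_stack([nn.end_times_s, nn.nn_ms, nn.valid.astype(int)])
        np.savetxt(fh, rows, fmt=[_FLOAT_FMT, _FLOAT_FMT, "%d"], delimiter=",")


def read_ibi_text(path: str | Path, source: str = "wearable") -> NNSeries:
    path = Path(path)
    meta, n_header = _read_header(path)
    df = pd.read_csv(path, skiprows=n_header)
    ends = df["beat_time_s"].to_numpy(dtype=float)
    nn_ms = df["nn_ms"].to_numpy(dtype=float)
    first = meta.get("first_beat_time_s", ends[0] - nn_ms[0] / 1000.0)
    times = np.concatenate([[first], ends])
    return NNSeries(
        beat_times_s=times,
        nn_ms=nn_ms,
        valid=df["valid"].to_numpy(dtype=bool),
        source=source,
    )


def write_table(path: str | Path, df: pd.DataFrame, header: dict | None = None) -> None:
    """CSV with optional ``# key=value`` provenance lines before the header row."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True), newline="\n")


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
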