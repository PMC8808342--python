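import numpy as np
import pytest
from hypothesis import settings

from nighthrv import EcgSpec, TachogramSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def constant_tachogram(hr_bpm: float = 60.0, duration_s: float = 300.0, seed: int = 0) -> TachogramSpec:
    """Metronome rhythm: no modulation, no jitter."""
    return TachogramSpec(
        duration_s=duration_s,
        mean_nn_ms=60000.0 / hr_bpm,
        lf_amp_ms=0.0,
        hf_amp_ms=0.0,
        jitter_sd_ms=0.0,
        seed=seed,
    )


def clean_ecg_spec(hr_bpm: float = 60.0, duration_s: float = 300.0, **kw) -> EcgSpec:
    """Artifact-free ECG with default morphology (P/T bumps, mild noise)."""
    return EcgSpec(tachogram=constant_tachogram(hr_bpm, duration_s), **kw)


def bare_ecg_spec(hr_bpm: float = 60.0, duration_s: float = 300.0, **kw) -> EcgSpec:
    """R spikes only on a flat noise-free baseline (for constructed detector tests)."""
    kw.setdefault("p_amplitude_frac", 0.0)
    kw.setdefault("t_amplitude_frac", 0.0)
    kw.setdefault("baseline_wander_amp", 0.0)
    kw.setdefault("noise_sd", 0.0)
    return EcgSpec(tachogram=constant_tachogram(hr_bpm, duration_s), **kw)


def match_peaks(detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float = 0.05):
    """Greedy nearest matching of detected peak times to true beat times.

    Returns (sensitivity, positive predictivity, mean absolute timing error in
    seconds over matched pairs).
    """
    if detected_s.size == 0:
        return 0.0, 0.0, np.nan
    d = np.abs(detected_s[:, None] - truth_s[None, :])
    det_err = d.min(axis=1)
    matched_det = det_err <= tol_s
    matched_truth = d.min(axis=0) <= tol_s
    sens = matched_truth.mean()
    ppv = matched_det.mean()
    mae = det_err[matched_det].mean() if matched_det.any() else np.nan
    return float(sens), float(ppv), float(mae)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
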