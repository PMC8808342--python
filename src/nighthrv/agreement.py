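"""Device-agreement statistics: Pearson r, fitted-line r-squared, Bland-Altman.

Conventions, fixed once for the whole package:

* differences are wearable minus reference, so a wearable that underestimates
  a parameter shows a negative mean bias;
* the regression puts the reference (ECG) on the abscissa and the wearable on
  the ordinate; the identity line y = x is the ideal;
* limits of agreement are mean bias +/- 1.96 x SD of the differences (the
  interval expected to contain 95% of between-device differences), not a
  confidence interval of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSamples",
    "AgreementReport",
    "pair_windows",
    "pearson",
    "regression_r2",
    "bland_altman",
    "compute_agreement",
    "correlation_strength",
    "agreement_table",
    "scatter_plot",
    "bland_altman_plot",
]

LOA_Z = 1.96  # normal 95% coverage factor for limits of agreement


@dataclass(frozen=True)
class PairedSamples:
    """Matched wearable/reference values for one parameter.

    ``unit_ids`` identify each pair's window (night_id, window_start) or night;
    incomplete units were dropped during pairing and counted in ``n_dropped``.
    """

    parameter: str
    wearable: np.ndarray
    reference: np.ndarray
    unit_ids: tuple
    granularity: str = "window"  # or "night"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.wearable, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        object.__setattr__(self, "wearable", w)
        object.__setattr__(self, "reference", r)
        if w.size != r.size:
            raise ValueError("wearable and reference must be equal length")
        if np.isnan(w).any() or np.isnan(r).any():
            raise ValueError("paired samples must not contain missing values")

    @property
    def n(self) -> int:
        return int(self.wearable.size)


@dataclass(frozen=True)
class AgreementReport:
    parameter: str
    granularity: str
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r outside [-1, 1]")


def _values(obj, parameter: str) -> float:
    return obj.value(parameter)


def pair_windows(wearable, reference, parameter: str) -> PairedSamples:
    """Inner join of two channels' windows (or nights) on their unit key.

    Accepts lists of :class:`~nighthrv.hrv.HRVWindow` (key: night_id + window
    start) or :class:`~nighthrv.hrv.NightSummary` (key: night_id). Units that
    are gated out, missing on either side, or missing this parameter's value
    are dropped and counted.
    """

    def collect(items):
        out = {}
        for it in items:
            if getattr(it, "gated_out", False):
                continue
            if hasattr(it, "window_start_s"):
                key = (it.night_id, round(float(it.window_start_s), 3))
            else:
                key = it.night_id
            out[key] = _values(it, parameter)
        return out

    wmap, rmap = collect(wearable), collect(reference)
    all_keys = set(wmap) | set(rmap)
    keys = sorted(k for k in all_keys if k in wmap and k in rmap
                  and not math.isnan(wmap[k]) and not math.isnan(rmap[k]))
    if not keys:
        raise ValueError(f"no overlapping complete units for parameter {parameter!r}")
    first = next(iter(wearable), None) or next(iter(reference))
    granularity = "window" if hasattr(first, "window_start_s") else "night"
    return PairedSamples(
        parameter=parameter,
        wearable=np.array([wmap[k] for k in keys]),
        reference=np.array([rmap[k] for k in keys]),
        unit_ids=tuple(keys),
        granularity=granularity,
        n_dropped=len(all_keys) - len(keys),
    )


def pearson(pairs: PairedSamples) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(pairs.wearable) == 0 or np.std(pairs.reference) == 0:
        raise ValueError("degenerate sample: zero variance")
    r, p = stats.pearsonr(pairs.wearable, pairs.reference)
    return float(r), float(p)


def regression_r2(pairs: PairedSamples, wearable_on_x: bool = False) -> tuple[float, float, float]:
    """Ordinary least squares of wearable on reference; returns (slope, intercept, r2).

    r2 is computed explicitly as 1 - SS_res/SS_tot of the fit (for simple OLS
    this equals the squared Pearson correlation). ``wearable_on_x`` swaps the
    orientation for sensitivity analysis.
    """
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    x, y = (pairs.reference, pairs.wearable) if not wearable_on_x else (pairs.wearable, pairs.reference)
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero abscissa variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return float(fit.slope), float(fit.intercept), r2


def bland_altman(pairs: PairedSamples) -> tuple[float, float, float, float]:
    """Mean bias, SD of differences and 95% limits of agreement.

    Differences are wearable - reference; limits are bias +/- 1.96 SD.
    """
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    d = pairs.wearable - pairs.reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - LOA_Z * sd, bias + LOA_Z * sd


def compute_agreement(pairs: PairedSamples) -> AgreementReport:
    """All three agreement statistics for one parameter's paired samples."""
    r, p = pearson(pairs)
    slope, intercept, r2 = regression_r2(pairs)
    bias, sd, lo, hi = bland_altman(pairs)
    return AgreementReport(
        parameter=pairs.parameter,
        granularity=pairs.granularity,
        n=pairs.n,
        pearson_r=r,
        p_value=p,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mean_bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
    )


def correlation_strength(r: float) -> str:
    """Interpretive label for a positive correlation (convenience only).

    >= 0.7 high, 0.5-0.7 moderate, < 0.5 low. Never used for gating.
    """
    if r >= 0.7:
        return "high"
    return "moderate" if r >= 0.5 else "low"


def agreement_table(reports: list[AgreementReport]) -> pd.DataFrame:
    """One row per parameter: n, r, p, slope, intercept, r2, bias, SD, limits."""
    rows = [
        {
            "parameter": rep.parameter,
            "n": rep.n,
            "pearson_r": rep.pearson_r,
            "p_value": rep.p_value,
            "slope": rep.slope,
            "intercept": rep.intercept,
            "r_squared": rep.r_squared,
            "mean_bias": rep.mean_bias,
            "sd_diff": rep.sd_diff,
            "loa_low": rep.loa_low,
            "loa_high": rep.loa_high,
            "correlation_strength": correlation_strength(rep.pearson_r),
        }
        for rep in reports
    ]
    return pd.DataFrame(rows)


def scatter_plot(pairs: PairedSamples, report: AgreementReport, path) -> None:
    """Reference-vs-wearable scatter with the fitted line (red) and y=x (black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs.reference, pairs.wearable, s=8, alpha=0.5)
    lim = np.array([min(pairs.reference.min(), pairs.wearable.min()),
                    max(pairs.reference.max(), pairs.wearable.max())])
    ax.plot(lim, report.slope * lim + report.intercept, "r-", label=f"fit (r²={report.r_squared:.2f})")
    ax.plot(lim, lim, "k-", lw=1, label="ideal y=x")
    ax.set_xlabel(f"reference (ECG) {pairs.parameter}")
    ax.set_ylabel(f"wearable {pairs.parameter}")
    ax.set_title(f"{pairs.parameter} ({pairs.granularity} level, n={pairs.n})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(pairs: PairedSamples, report: AgreementReport, path) -> None:
    """Pair means vs differences with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = (pairs.wearable + pairs.reference) / 2.0
    diff = pairs.wearable - pairs.reference
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=8, alpha=0.5)
    ax.axhline(report.mean_bias, color="r", label=f"bias {report.mean_bias:.2f}")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="gray", ls="--")
    ax.set_xlabel(f"pair mean {pairs.parameter}")
    ax.set_ylabel("wearable − reference")
    ax.set_title(f"{pairs.parameter} ({pairs.granularity} level)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
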