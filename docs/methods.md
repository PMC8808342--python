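# Methods

`nighthrv` validates a wearable's nocturnal heart-rate (HR) and heart-rate-
variability (HRV) output against a reference single-lead ECG. This note
describes the models and procedures, the parameters that matter, what the
synthetic study emulates (and does not), and the numerical choices made where
the design was genuinely open.

## Problem setting

A participant sleeps wearing both devices. The ECG channel yields a raw
waveform (default 512 Hz) from which beats must be detected; the wearable
yields per-5-minute HR/RMSSD values plus a beat-by-beat interbeat-interval
(IBI) export with per-sample validity flags. Both channels are reduced to the
same eight parameters per 5-minute window — HR, RMSSD, AVNN, SDNN, pNN50, LF,
HF, LF:HF — and compared per window and per night with three agreement
statistics: Pearson correlation, an ordinary-least-squares fit of wearable on
reference with its r², and Bland–Altman bias with 95% limits of agreement
(bias ± 1.96·SD of the differences; differences are wearable − reference).

## ECG processing

1. **Filtering.** Butterworth band-pass, 0.5–100 Hz, order 4, applied
   forward-backward (zero phase) so R-peak latency is not shifted. With a
   512 Hz input the 100 Hz cutoff sits below Nyquist; lower sampling rates must
   lower the cutoff or the filter refuses.
2. **Windowing.** Non-overlapping 300-s windows aligned to the recording
   start; a trailing partial window is dropped.
3. **Two-round peak detection.** Round 1 collects every strict local maximum
   above the window's mean amplitude — a deliberate superset (R plus P/T/noise
   peaks). Round 2 uses the mean round-1 peak amplitude as a reference: peaks
   below θ = 0.5 of it are dropped; of any two survivors closer than the
   refractory period (300 ms, the 200-bpm bound) the larger is kept (ties:
   earlier); gaps longer than 1200 ms (the 50-bpm bound) are re-scanned and the
   largest round-1 peak above θ′ = 0.3 of the reference is re-admitted, if it
   sits at least one refractory period from both gap edges (without that
   guard, admit/remove cycles are possible). The steps iterate to a fixed
   point; the procedure is idempotent and invariant to amplitude scaling, and
   its output is always a subset of round-1 positions. Finally, peaks within
   one refractory period of a window edge are discarded: they cannot be
   refractory-checked against the neighbouring window, and every orphan P/T
   false positive produced by cutting a beat complex at a window boundary
   falls inside that margin. The cost is at most the first/last beat of a
   window (≤ 2 of ~300), which only shortens the interval series.
4. **Window validation.** A window is accepted iff (a) its gross beat rate
   (peak count over duration) **and** the rate implied by the mean in-range RR
   interval both lie in 50–200 bpm; (b) the window kurtosis is ≥ 5; (c) the
   peak-amplitude coefficient of variation is ≤ 0.25; and (d) at least 80% of
   RR intervals lie in 300–1200 ms. Criteria (b) and (c) are
   signal-quality-index components added because the rate/range criteria alone
   provably cannot reject dense noise: the refractory rule converts burst
   maxima into plausible 300–400 ms intervals that pass every rate check,
   while a mostly-flat dropout window passes the RR-mean check. A clean
   synthetic window has kurtosis ≈ 18 and amplitude CV ≈ 0.013; burst- or
   noise-dominated windows fall to kurtosis ≈ 3 (the Gaussian value) and CV ≥
   0.15, so the defaults (5 and 0.25) sit in a wide separation band. All
   thresholds are exposed in `StudyConfig`.

Individual RR intervals outside 300–1200 ms are flagged invalid; an invalid
interval breaks adjacency on both sides for successive-difference statistics.

## HRV parameters

Per window, over valid NN intervals: AVNN (mean), HR = 60000/AVNN, SDNN
(sample SD, n−1), RMSSD (RMS of differences over adjacent valid pairs), and
pNN50 = (#adjacent pairs with |Δ| > 50 ms) / (total NN intervals) — note the
denominator is the interval count, not the pair count, and the value is a
proportion in [0, 1]. For the wearable channel, HR and RMSSD come from the
device's own window-level export, not recomputed from IBI.

Frequency domain: a Lomb–Scargle periodogram of the unevenly sampled NN
series (abscissa: each interval's closing beat time), which needs no
interpolation over gapped wearable IBI. The unnormalized periodogram is scaled
by 2T/N so that integrating a pure sinusoid's spectral peak recovers its power
A²/2 and integrating white noise over the full band recovers its variance; band
powers are rectangle-integrated on a grid oversampled 8× relative to the 1/T
resolution. LF is [0.04, 0.15) Hz, HF [0.15, 0.4] Hz (0.15 counted once, in
HF); LF:HF is NaN when HF is zero. A 4-Hz cubic-spline + Welch estimator is
selectable for sensitivity analysis. The frequency domain requires ≥ 30 NN
intervals spanning ≥ 120 s — a floor below which band estimates at 0.04 Hz are
meaningless.

Wearable windows are analyzed only if at least 30% of their IBI samples are
valid (boundary inclusive). Nightly summaries are unweighted means over
non-gated windows, with per-parameter missingness handled independently.

## Synthetic paired study

The generator defines the study conditions; it is parameter-free ground truth,
not a physiological simulator.

* **Tachogram.** NN_k = mean_nn + A_LF·sin(2πf_LF·t_k) + A_HF·sin(2πf_HF·t_k)
  + ε_k with t_k the cumulative beat time and ε_k ~ N(0, σ²). Defaults: 1000 ms
  mean (60 bpm), A_LF = 40 ms at 0.095 Hz, A_HF = 30 ms at 0.25 Hz, σ = 15 ms —
  a healthy sleeping adult with SDNN ≈ 38 ms and RMSSD ≈ 40 ms. Closed forms
  for SDNN/RMSSD/LF/HF under these assumptions are exposed for recovery tests.
  Because beats sample the sinusoid with a length bias, the realized mean NN
  sits ~0.3% below nominal at default amplitudes; the exact beat-count
  relation holds for the unmodulated rhythm.
* **ECG waveform.** Per beat: a Gaussian R spike (σ = 12 ms, amplitude 1), a
  P bump (−180 ms, 0.15) and a T bump (+220 ms, 0.30); plus 0.33 Hz baseline
  wander (amp 0.05), white noise (SD 0.02), optional artifact bursts
  (segment-local white noise) and dropout gaps (flat zero; beats inside are
  flagged, not dropped). The rhythm starts 0.3 s after recording start — a
  recording never begins exactly on an R peak, and a deflection at sample 0 is
  not a detectable local maximum.
* **Wearable channel.** Window-level parameters are ground truth plus an
  additive per-parameter bias and Gaussian noise; this makes agreement-
  statistic recovery targets exactly known for all eight parameters. Default
  biases/SDs are set at the error scale of a finger-PPG ring against a chest
  ECG during sleep (e.g. HR −0.44 ± 1.21 bpm, RMSSD −15 ± 15 ms, with spectral
  parameters an order of magnitude noisier) and are never adjusted. IBI
  invalidity is laid down as one contiguous run per window (motion-artifact
  episodes), sized by `invalid_fraction`. Noisy wearable values are not
  clamped to physical ranges; clamping would bias the recovered bias.
* **Study.** 35 nights; each night redraws the participant's mean NN
  (SD 70 ms) and rescales modulation amplitudes (lognormal, relative SD 0.2),
  giving the between-participant spread without which between-device
  correlations would be meaningless. Default nights are 16 windows (4800 s)
  long — long enough that per-night averaging shows its variance shrink while
  the full study runs in well under a minute; the pipeline handles 8-hour
  nights identically.

What the generator does **not** emulate: realistic PQRST morphology,
respiration-coupled HF dynamics, sleep-stage-dependent HRV, ectopy, or the
wearable's internal PPG processing (its error model is additive by
construction). Passing tests therefore demonstrate that the pipeline recovers
known signals and injected error structure — not that any physical device
meets these error levels on real data.

## Numerical and design choices

* Zero-phase filtering, θ = 0.5, θ′ = 0.3, φ = 0.8 (valid-RR fraction),
  refractory 300 ms and search-back 1200 ms all config-exposed; θ/θ′ chosen so
  clean synthetic ECG is detected at 100% sensitivity with T waves present.
* Round-1 "peaks" are strict local maxima of the signed filtered signal above
  the window mean (the only testable reading; no rectification).
* Regression puts the reference on the abscissa; r² is computed as
  1 − SS_res/SS_tot (equal to squared Pearson r for simple OLS — asserted, not
  assumed). The difference sign convention makes a wearable that
  underestimates show negative bias.
* The 95% interval reported with Bland–Altman statistics is the pair of
  limits of agreement (bias ± 1.96·SD of differences), not a confidence
  interval of the mean bias: at window-level n in the hundreds a CI of the
  mean would be an order of magnitude narrower than the spread the statistics
  describe.
* Agreement analyses pool windows across nights without modelling
  within-participant correlation; the per-night analysis is the robustness
  check for that pooling.
* p-values are reported, never used for gating; the high/moderate/low
  correlation labels (0.7/0.5 cut points) are interpretive convenience only.
* Determinism: all randomness flows from explicit seeds through
  `numpy.random.Generator`; rerunning a study with the same config + seed
  reproduces every output file byte for byte, and each table carries a config
  hash in its header.

## Known limitations

* The window-validity thresholds (φ, kurtosis, amplitude CV) were set from
  the synthetic clean/corrupt separation; real ECG with low-voltage QRS or
  pathological morphology may need different values.
* pNN50's interval-count denominator follows the definition used by the
  wearable-validation literature this package targets; values are not directly
  comparable to implementations dividing by the pair count.
* The edge guard trades up to two boundary beats per window for immunity to
  boundary P/T false positives; per-window NN counts are correspondingly
  ~1 lower than the beat count.
* LF:HF is the noisiest derived quantity: small band-power estimation errors
  amplify through the ratio, and its agreement statistics are correspondingly
  the weakest — mirroring its behaviour in real device-validation studies.
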