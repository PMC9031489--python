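# Methods

This note documents the models, parameter choices and numerical decisions
behind `neohrv`, and what the synthetic validation does and does not show.

## Problem setting

Single-lead NICU ECG at a nominal 128 Hz, with expert seizure annotations
as onset/offset intervals (seconds from record start, half-open
`[onset, offset)`). The record is tiled with non-overlapping epochs of
L = 60 s or 180 s; the trailing partial window is discarded. An epoch is a
*seizure epoch* under one of three rules: any overlap with an event
(`any_sample`, the default), at least 10 s of total overlap (`min_10s`,
the conventional minimum electrographic seizure duration), or at least L/2
(`half_window`). The rules are strictly ordered: any-sample labels at
least as many seizure epochs as min-10 s, which labels at least as many as
half-window (for L = 60 the latter two compare 10 s against 30 s).

Clock durations (`HH:MM:SS`) are held as integer seconds. In cohort
summaries the mean seizure duration per patient uses round-half-up to the
nearest second and the mean record length uses truncation; these are the
conventions under which the bundled 51-newborn reference summary's printed
totals and means are reproduced exactly. Printed per-patient mean event
durations are themselves rounded to whole seconds, so per-group seizure
totals are carried as separate inputs where exactness matters.

## QRS detection

Classic Pan–Tompkins cascade: zero-phase Butterworth band-pass 5–15 Hz
(order 2), five-point derivative, squaring, moving-window integration, and
adaptive dual-threshold peak picking on the integrated signal with
search-back at half threshold when the gap since the last beat exceeds
166 % of the running 8-beat RR average. R times are refined to the local
maximum of the band-passed signal around each accepted integration peak.
Parameters are adapted minimally to neonatal rates (100–200 bpm):
integration window 100 ms (shortened from the adult 150 ms), refractory
period 200 ms, threshold learning over the first 2 s. No ectopic-beat or
artifact correction is applied afterwards; the chain is fully automatic.
Detection runs over the whole record and the resulting R-peak list is
sliced per epoch (avoids edge losses in short epochs); per-epoch detection
is available for ablation. A peak exactly on an epoch boundary belongs to
the epoch starting there.

On synthetic ECG the detector recovers the exact beat count noise-free and
≥ 99 % sensitivity / positive predictivity at ±40 ms with noise RMS 0.05
(see `neohrv.validation.pan_tompkins_benchmark`).

## Feature battery

Per epoch, from the RR series in ms (fewer than the stated minimum of
beats makes the affected features missing, never an exception):

- **Time domain** (≥ 3 intervals): SDNN and SDSD as sample standard
  deviations (n−1), RMSSD, pNN50 (% of successive differences with
  |Δ| > 50 ms), HR = 60000 / mean RR.
- **Geometry** (≥ 20 intervals): RR histogram with bin width
  1000/128 ≈ 7.8125 ms (one sample at the nominal acquisition rate,
  the standard HRV convention). TRI = N / max bin count; TINN is the base
  width of the least-squares triangular fit with apex fixed at the mode
  and both base points searched exhaustively over bin centers. A
  single-bin histogram degenerates to TRI = 1, TINN = one bin width.
- **Poincaré** (≥ 3 intervals): SD1 = SDSD/√2,
  SD2 = √(2·SDNN² − SDSD²/2) (clipped at 0), ratio SD1/SD2 missing when
  SD2 = 0.
- **Correlation dimension** (≥ 100 intervals): Grassberger–Procaccia with
  embedding dimension 2 and delay 1; CD is the least-squares slope of
  log C(ρ) against log ρ over 12 log-spaced radii spanning the 1st–25th
  percentile of pairwise distances. The window sits deliberately at small
  radii: at larger radii C saturates toward 1 and the slope is biased low
  (an i.i.d. series, which should fill the plane with CD ≈ 2, drops to
  ≈ 1.5 when fitting out to the 90th percentile). CD is the least
  constrained feature of the battery — no standard fixes the estimator —
  so these settings are exposed and should not be compared across
  implementations.
- **Frequency domain** (≥ 10 intervals spanning at least half the epoch):
  the RR tachogram (value RRᵢ at the time of the i-th peak's successor) is
  linearly interpolated, resampled at 8 Hz over the epoch grid
  (comfortably above twice the 1.3 Hz band edge), mean-removed, and
  analyzed with an unwindowed FFT periodogram. Band powers integrate the
  piecewise-linear spectrum over the half-open neonatal bands VLF [0,
  0.04), LF [0.04, 0.3), HF [0.3, 1.3) Hz, sharing edge values so
  VLF + LF + HF = TotalPower exactly; pLF and pHF are percentages of
  (TotalPower − VLF) and sum to 100 when defined; LF/HF is missing when
  HF = 0.
- **Entropies**: SampEn (m = 2, self-matches excluded, n−m templates at
  both lengths) and ApEn (self-matches included) both use *strict*
  Chebyshev distance < r with r = 0.2 × SD of the epoch's scale-1 RR
  series. The 0.2 tolerance is interpreted as a fraction of the series SD
  — the field convention — rather than an absolute value; with a strict
  inequality a constant series still scores 0 for all three estimators
  since every distance is 0 < r. DistEn uses m = 2, delay 1, and M = 512
  equal-width bins spanning [0, max observed distance] (the bin range is
  not standardized; anchoring at the observed maximum makes the estimator
  translation- and scale-invariant), normalized by log₂ M into [0, 1].
  Multiscale versions apply the estimators to non-overlapping block means
  at scales 1–4 (180 s epochs) or scale 1 only (60 s), keeping r fixed at
  the scale-1 value; a scale whose coarse-grained series has fewer than
  100 points is missing, which is why 60 s epochs stop at scale 1 for
  neonatal rates. All three estimators (and the plug-in mutual
  information) are verified against naive O(n²) transcriptions of their
  definitions to < 10⁻¹² on hundreds of random series.

The named vector has 18 base features plus MSE/MDE: 20 fields at 60 s, 26
at 180 s.

## Classification and validation

Per LOSO fold (one fold per patient, controls included as test subjects),
fitted on the training patients only: z-scoring by training mean/SD
(zero-variance columns map to 0), mean imputation (0 after z-scoring;
fully missing columns are zeroed with a log entry), and greedy mRMR
ranking under the MID criterion — add the feature maximizing MI(f; class)
minus the mean MI with the already-selected set. MI uses equal-frequency
discretization into 10 bins; columns with ≤ 10 distinct values keep one
code per value (pure quantile binning collapses near-binary features into
a single bin and destroys their information); missing values form their
own code. Ties in the greedy step break toward the earlier column in the
canonical feature order, making the ranking deterministic.

Classifiers are scikit-learn SVC behind the module surface: the linear
variant maps the regularization penalty λ to a margin cost 1/(λ·n_train);
the Gaussian variant uses box constraint C and kernel
k(u,v) = exp(−‖u−v‖²/2·scale²) (γ = 1/(2·scale²)). Class imbalance is
handled by per-class misclassification costs C₁ (non-seizure) and C₂
(seizure) as class weights. Decision scores are the signed margin (larger
= more seizure-like); hard labels are score > 0. Grid search evaluates
every (hyper-parameter, feature-count) pair by LOSO and selects the
highest mean per-pathological-patient AUC — AUC is undefined for
all-negative control records, so controls are excluded from the selection
mean but still contribute to specificity, FDR/FDH and the concatenated
AUC — breaking ties toward fewer features, then smaller C₂.

## Evaluation conventions

Predicted events are maximal runs of consecutive predicted-positive
epochs; one negative epoch splits runs. A predicted event is false when it
overlaps no expert event; FDR is false predicted events over all predicted
events (missing when nothing is predicted; an alternative per-expert-event
denominator is not used), and FDH normalizes by the analyzed (tiled)
record duration, not the raw file length. An expert event is detected when
any predicted-positive epoch overlaps it, whether or not that epoch's own
ground-truth label is seizure; the detection delay is the end of the
earliest such epoch minus the expert onset, hence bounded by the event
duration plus one epoch length. Cohort figures are reported as mean ±
standard error across pathological patients.

## Synthetic cohort generator

Beat-to-beat RR model:
RR(t) = RR₀ + a_LF·sin(2π f_LF t + φ₁) + a_HF·sin(2π f_HF t + φ₂) + ε(t),
with per-patient baseline heart rate uniform in 110–170 bpm (inside the
physiological neonatal 100–200 bpm), modulation frequencies drawn inside
the LF (0.05–0.25 Hz) and HF (0.35–1.2 Hz) bands, depths a_LF = 15 ms and
a_HF = 10 ms, and white jitter σ = 10 ms — together an SDNN of ~15–20 ms,
a typical resting neonatal scale. During annotated events RR₀ is divided
by the heart-rate gain (default 1.15) and all variability terms are
multiplied by the variability gain (default 0.5), switching instantly at
onset/offset (a ramp hook exists, default 0; pre/post-ictal drift is out
of scope). Configurations whose deterministic envelope admits RR < 250 ms
are rejected; jitter tails are clamped at 250 ms. Event counts are
1 + Poisson(3.2) per pathological patient (mean ≈ 4.2, matching the
reference cohort's 92 events over 22 patients) and durations are
log-normal(μ = 4.28, σ = 0.74), giving ≈ 40 % of events under 60 s and
≈ 89 % under 180 s. ECG rendering sums Gaussian templates at the true beat
times (R: amplitude 1, σ = 10 ms; P/T bumps at fixed fractions of the
local RR) plus white noise (default RMS 0.05). One master seed spawns
per-patient independent streams, so cohorts are bit-reproducible.

The generator deliberately emulates only the first/second-order structure
the feature battery measures — mean rate, band-limited oscillation power,
jitter entropy, and their ictal modulation. It does **not** model ECG
artifacts, electrode motion, ectopic beats or arrhythmias, respiratory
non-stationarity, or gradual autonomic drift around seizures. Passing the
synthetic end-to-end checks therefore demonstrates that the pipeline's
machinery is correct and can recover a planted autonomic signature; it
says nothing about detection performance on clinical recordings, where
published ECG-only systems reach per-patient AUCs near 0.6, far below the
near-perfect synthetic recovery here.

## Validation problem sizes

The packaged validation suite uses: 200 random series of length ≤ 50 for
the estimator-vs-oracle checks; 60 s/120-beat noise-free and 180 s noisy
records for the QRS benchmark; and a 35-patient cohort (20 controls, 15
pathological, 45 min each at 128 Hz) for the end-to-end planted-effect
recovery, scored as the mean per-pathological-patient AUC of the best of a
small 180 s Gaussian grid (box 1; scale 1 or 3; C₂ 1 or 5; top-2 mRMR
features) under the any-sample rule. The null calibration repeats the run
with both gains at 1 under a fixed configuration (box 1, scale 1, C₂ 5,
2 features). With ~15 epochs and ~4–7 positive epochs per patient the
per-patient null AUC has substantial variance; the 15-patient mean has a
Monte-Carlo standard deviation of roughly 0.03, so single-seed estimates
occasionally fall slightly outside 0.5 ± 0.05 even though the expectation
is exactly 0.5.

## Known limitations

- The correlation-dimension estimate depends strongly on its scaling
  window and embedding; values are internally consistent but not
  comparable across toolkits.
- TINN's exhaustive triangular fit is O(bins²) and resolves the base width
  only to about one histogram bin.
- Epoch-level dispersion features (SDNN, TRI) can *increase* in epochs
  straddling an event boundary — the step change in mean RR adds variance
  even while within-event variability is suppressed — so directional
  effect checks compare strictly within-event segments or half-window
  epochs.
- The EDF writer is minimal (16-bit, 1 s records, integer sampling rates)
  and intended for round-trip testing and export of synthetic cohorts, not
  for clinical archiving.
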