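# Methods

This note documents the models, parameter choices and numerical conventions
behind `mtfse`, and what the synthetic tests do and do not establish.

## Signal model and preprocessing

The HRV signal is the series of RR intervals (ms) with each interval attached
to the time of the beat that ends it — the conventional tachogram sample
points. Invariants enforced throughout: beat times strictly increasing, all
intervals positive, `rr[i] = (t[i+1] − t[i])·1000`.

**Artifact removal.** Automatic beat detection produces spurious intervals
(missed beats double an interval, false detections halve one). An interval
deviating from the median of its 5-beat centered window (window clipped at the
series edges) by more than 20% of that median is replaced by the median, and
beat times are rebuilt by cumulative summation from the first beat. Both
parameters are configurable (`median_window`, `median_rel_threshold`); 5 beats
/ 20% is standard ectopic-rejection practice. The filter preserves series
length and is idempotent on the series it produces.

**Segmentation and labeling.** Records are tiled into consecutive,
non-overlapping 5-minute windows aligned to minute boundaries (half-open
`[start, start+300)`; minute m covers `[60m, 60(m+1))`). This matches the
granularity of per-minute apnea annotations and is the simplest reproducible
convention — the source protocol does not state alignment or overlap, so exact
segment counts on real data may differ from other implementations. Windows of
apnea-patient records (class A) with at least one apneic minute are labeled
A-OSA, apnea-free ones A-N; apnea-free control (class C) windows are C-N and
apneic control windows are discarded. Trailing partial windows are discarded.

**Resampling.** AR spectral estimation needs uniform sampling, so each window
is cubic-spline interpolated through its (beat time, RR) knots and evaluated
on a 4 Hz grid (1200 samples). 4 Hz is the standard tachogram rate: it is
comfortably above twice the 0.4 Hz analysis limit while keeping segments
short. Windows with fewer than 4 beats cannot support a cubic spline and are
rejected, as are windows whose spline output is non-positive or non-finite
(the spline extrapolates between the window edge and the first/last beat; on
physiological data this extrapolation is benign).

## Burg-AR spectrum and the TFSI

The AR model `x(t) = −Σ aₖ x(t−k) + u(t)` gives the all-pole PSD
`S(f) = δ²/|1 + Σ aₖ e^{−2πifk/fs}|²`. Burg's lattice recursion estimates the
aₖ by minimizing the summed forward+backward prediction-error power at each
stage; the closed-form stage optimum keeps every reflection coefficient inside
the unit circle, so the fitted model is always stable. The signal mean is
removed per window before fitting (AR estimation assumes zero mean). δ² is
the final prediction-error power, which for white noise equals the signal
variance; with this convention the PSD mean over the full Nyquist grid tracks
the signal variance (verified within 20% in tests).

Order 16 at 4 Hz is the established choice for short HRV segments and is the
default (`ar_order`). Degenerate inputs — constant windows, order ≥ n/2 —
raise errors naming the offending window.

**TFSI windowing.** The time axis of the image comes from a sliding window:
64 s length (256 samples ≫ 2·16, stable AR(16) fits, ≈0.016 Hz Fourier-scale
resolution in the VLF band) and 4 s hop, giving 60 rows per 5-minute segment —
enough texture for 2-D entropy. The frequency axis is 256 uniform points on
[0, 0.4] Hz. All three are configuration knobs (`tfsi_window_s`, `tfsi_hop_s`,
`n_freq`) and are recorded in every exported artifact, because no standard
exists for this choice.

## Entropy indices

Each (sub-)image is reduced to the Shannon entropy of its quantized pixel
intensities. Quantization is linear into K = 256 equal-width bins spanning the
range of the **total** image (values at the maximum fall in the top bin), the
range being shared by all sub-images so their entropies are comparable and the
ratio indices meaningful. Entropies use log base 10, putting the maximum
possible value at log₁₀ 256 ≈ 2.41. K, base and the band edges are
configurable; the defaults are documented choices, since the underlying
discretization of "the value of the power spectrum" is not standardized —
absolute index values are therefore implementation-specific, while ordering
and separability are the meaningful outputs.

Band membership is half-open — VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4]
with 0.4 Hz itself an HF pixel — so every frequency column belongs to exactly
one band.

Ratio indices are exact quotients of the returned entropies. When a
denominator entropy is zero (e.g. a constant sub-image), the ratio is reported
as *missing* (None/empty CSV field) rather than NaN or a sentinel: degenerate
segments must be visible, not contagious. Rows with missing indices are
excluded (and counted) by the evaluation stage.

Because quantization is per-total-image and linear, every index is invariant
under multiplying the whole TFSI by a positive constant; the PSD scaling
convention therefore cannot affect the features.

## Synthetic generator

`generate_rr` builds a continuous tachogram r(t) = mean RR + sinusoids
(VLF/LF/HF components), optionally amplitude-modulated by an "apnea cycle"
(period 25–60 s — the cyclical-variation timescale of obstructive events;
modulation factor `1 − depth/2 + (depth/2)·cos(2πt/T)`, troughs at T/2 + kT).
Beats are emitted integrate-to-threshold style (IPFM-like): the next beat
follows after r(t)/1000 seconds plus white jitter, so beat times are
irregular and genuinely exercise the spline/resampling path. Ectopic-like
artifacts double randomly chosen intervals at a configurable per-beat rate.
Minutes containing a modulation trough are annotated apneic, giving the
labeling stage real work. Everything derives from a single seed; cohort
members use seeds derived from the cohort seed and member index.

Default cohort templates (fixed once, from the sympathetic/parasympathetic
physiology of OSA): *apnea-like* — mean RR 900 ms, LF-dominant (0.10 Hz,
50 ms) with suppressed HF (0.25 Hz, 10 ms), apnea cycle (45 s, depth 0.25),
jitter 15 ms, ectopic rate 0.005/beat; *normal-like* — mean RR 850 ms,
HF-dominant (0.25 Hz, 40 ms) with modest LF (0.10 Hz, 15 ms), no apnea cycle,
jitter 10 ms.

**What the generator does not emulate:** real apnea physiology
(bradycardia–tachycardia waveform shape, arousal transients, respiratory
coupling), non-stationarity across the night, subject-level variation, or
realistic detector noise. A green synthetic test therefore establishes that
the pipeline is *correct and sensitive to the designed spectral contrast* —
clean LF-dominant vs HF-dominant cohorts separate essentially perfectly — not
that any particular accuracy will be achieved on clinical recordings.

## Evaluation protocol

Welch's unequal-variance t-test is used for all group comparisons (group SDs
genuinely differ), with significance stars at 0.05/0.01/0.001. Zero-variance
degenerate comparisons report an undefined p rather than a number.

Classification: per repetition, n segments per group (default 300, reduced
with a warning to the smallest group) are drawn without replacement, one
stratified 10-fold pass is run, fold confusion counts are summed, and
Acc = (TP+TN)/all, Sen = TP/(TP+FN), Spe = TN/(FP+TN) are computed (undefined
denominators flagged, not zeroed); reported values are means over repetitions
(default 500). Folds are over segments, not subjects — segments of one subject
can appear in both train and test folds, an optimistic-leakage caveat
inherited from the protocol being reproduced. Multi-group tasks report
one-vs-rest Sen/Spe/Acc per class, their macro means, and the row-normalized
classification-rate table. KNN/SVM/DT run at scikit-learn defaults, logged
verbatim into every report; the decision tree additionally receives a
seed-derived `random_state` so identical seeds give identical reports.

Chance-level checks use the permutation-null *mean*: a single fixed
permutation of 200 labels freezes a hypergeometric class imbalance worth
~3.5 accuracy points of SD, so chance behavior is asserted on the mean over
20 independent permutations.

## Numerical conventions and edge cases

- Burg stage with vanishing prediction error (pure deterministic signal)
  raises rather than emitting NaN coefficients.
- PSD evaluation accepts |f| ≤ Nyquist (S is even in f) and rejects anything
  beyond.
- Entropy of an image whose quantization range collapses to a point is 0.
- `remove_artifacts` requires at least one full filter window of intervals.
- All pipeline stages are deterministic: identical inputs and configuration
  produce bit-identical tachograms, TFSIs and feature CSVs.

## Known limitations

- Absolute entropy values depend on (K, log base, TFSI windowing); only
  comparisons under a fixed configuration are meaningful.
- Sub-image entropies can exceed the total-image entropy (they are computed
  over fewer pixels with the shared range), so ShEnpX is not bounded by 1.
- Segment-level cross-validation overstates subject-level generalization.
- The WFDB/ECG ingestion path requires the optional `wfdb` dependency and an
  external QRS detector; it is a convenience adapter, not a validated
  detection pipeline.
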