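# Methods

`hippofeat` implements an interictal stereo-EEG feature pipeline for
distinguishing epileptic (EH) from non-epileptic (NEH) hippocampus, together
with a synthetic cohort generator that makes every stage verifiable against
ground truth. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic validation does and does not
show about real recordings.

## Signal model and units

Signals are multi-channel iEEG in microvolts, assumed already referenced
(typically to the average of all intracranial contacts at acquisition). The
sampling rate must exceed 1.6 kHz because the analysis ceiling is 800 Hz;
clinical recordings at 5 kHz and synthetic validation at 2 kHz both satisfy
this. An optional common-average re-reference utility exists but is off by
default. All band-pass filtering is zero-phase (forward–backward
Butterworth, order 4 by default) so event latencies carry no group-delay
bias.

## HFO detection

Each channel is decomposed into `n_bands = 300` frequency bands with
geometrically spaced center frequencies between 60 and 800 Hz. Each band is
a constant-Q band-pass whose half-width is a fixed fraction of its center
(`band_halfwidth`, default 0.35). The analytic (Hilbert) amplitude envelope
of each band is z-scored against mean/SD estimated per consecutive 10-s
statistical window (`stat_window_s`); the final partial window reuses the
last complete window's statistics rather than estimating from a truncated
sample. Samples with z above `z_threshold = 3` form per-band suprathreshold
intervals; intervals that overlap in time in adjacent bands are joined into
time–frequency blobs (half-open interval convention: a single shared
boundary sample does not join). A blob becomes an event if

* its duration times its peak frequency strictly exceeds
  `min_cycles = 4` cycles, and
* its lowest member band is not the 60 Hz floor band (sharp transients such
  as interictal spikes excite a connected blob all the way down to the
  floor, so this rule discards spike leakage).

Events are labelled ripple (R) for peak frequency in [80, 250) Hz and fast
ripple (FR) for [250, 600) Hz; other events are excluded from features.

**Why wide, overlapping bands.** With 300 log-spaced centers, disjoint
bands would be ~0.9 % wide (1.5 Hz at 176 Hz). A filter that narrow has an
envelope response time of ~0.7 s, which cannot resolve events in the
15–40 ms range that ripple and fast-ripple oscillations occupy; every
detection would smear into hundreds of milliseconds. A constant-Q
half-width of 0.35 gives the envelope a time resolution of roughly 1.5
cycles of the center frequency. This serves the >4-cycle rule twice over:
genuine bursts stay above threshold long enough to pass, while chance
excursions of the background envelope (which last about the envelope
correlation time, i.e. only 1–2 cycles) fail it. At this half-width the
detector produces fewer than 10 spurious R+FR events per 10 minutes on pure
1/f noise while retaining >0.9 sensitivity to calibrated bursts.

**Implementation.** The zero-phase Butterworth magnitude response is
applied in the frequency domain together with the analytic-signal
construction (negative frequencies zeroed), one inverse FFT per band —
mathematically identical to filtfilt-then-Hilbert at a fraction of the
cost. The production path evaluates each band's envelope at a reduced
sampling rate via a short baseband inverse FFT of the band's spectral
support (the demodulated analytic signal, sampled without information loss;
envelope rate floored at 400 Hz, bounding interval quantization at
~2.5 ms), then converts suprathreshold intervals back to full-rate sample
indices.

**Event descriptors.** Relative amplitude is the blob's maximum envelope z
(unitless). Duration is the blob's full temporal span; a config flag
restricts it to the span within the peak band. Peak (dominant) frequency is
by default the z²-weighted geometric centroid of the member band centers:
with heavily overlapping bands, the center of the single argmax band is an
extreme-value statistic with ~+20 % bias and twice the variance of the
centroid on 1/f backgrounds (the argmax estimator remains available via
`peak_frequency_method="argmax"`).

## IED detection

A two-band scheme: the 1–35 Hz band sets a per-channel scaling factor
`scale = ref_background_uv / median(|x_1-35|)` that normalizes background
amplitude across channels (and makes detection gain-invariant); candidates
are extrema of the scaled 20–50 Hz band exceeding half the amplitude
threshold; a candidate is confirmed if, in a ±60 ms window of the scaled
wide-band signal, peak-to-trough amplitude exceeds `amp_threshold` (default
60 scaled µV against a reference background of 10 µV) and the transient
slope exceeds `slope_threshold` (default 3 scaled µV/ms). Events within a
200 ms refractory gap merge, keeping the larger. Reported amplitude is
peak-to-trough on the *unscaled* wide-band signal (a baseline-to-peak
option exists). The numeric thresholds are package defaults calibrated on
the synthetic spike templates to give ≥0.9 sensitivity and ≥0.8 precision
for spikes at three times the background SD; all are config-exposed. A
screening utility flags structures with ≥50 spikes/10 min for review
(strict inequality: 49.9 passes, 50 does not).

## Functional connectivity

Adjacent contact pairs (consecutive contact indices on one electrode) are
band-passed into R and FR bands and split into non-overlapping 1-s windows.
Per window and pair: the Pearson correlation, and the relative entropy
(Kullback–Leibler divergence) between the two windows' amplitude-sample
histograms. Histograms use 10 equal-width bins spanning the pooled range of
both windows, with additive smoothing ε = 1/(n·bins) on both probability
vectors so empty bins keep the divergence finite; natural log by default.
Relative entropy is directed; the per-pair feature uses the symmetrized
mean of both directions so results do not depend on contact ordering (both
directed values are retained in the long-format output). Windows with
constant input are recorded as missing and excluded from summaries. The
per-channel feature is the mean over all windows of all pairs including the
channel.

## Features and statistics

Fourteen features per channel and condition: R/FR rates (per 10 min,
normalized regardless of segment length), mean R/FR relative amplitude
(envelope z), dominant frequency (Hz), duration (ms), IED rate and mean
amplitude (µV), and R/FR correlation and relative entropy. Event-derived
means are missing — never zero — when a channel has no events of a class,
and such channels drop out of the affected test (a frequency of zero would
be meaningless).

When a subject performed several tasks, the grouped-task value is the mean
across tasks (missing values skipped). The battery runs per channel and,
as an outlier-robustness check, per hippocampus on channel medians (even
counts: mean of the central pair).

* Rest-vs-task change within each label: two-sided paired t-test.
* EH-vs-NEH within each condition: two-sided Mann–Whitney U.
* Discriminative value: ROC-AUC with EH positive, for rest values, task
  values, and rest-minus-task differences, computed by the rank identity
  (ties count one half). Significance against chance uses the
  Hanley–McNeil closed form with Q1 = A/(2−A), Q2 = 2A²/(1+A) evaluated at
  the observed AUC and a two-sided normal test. Note this variance is
  exactly symmetric under A ↔ 1−A only for equal group sizes. At small
  groups (≈10–25 per class) the test is mildly anti-conservative (null
  rejection ≈0.07–0.09 at α = 0.05), whereas the Mann–Whitney test is
  mildly conservative (≈0.04); the type-I calibration experiment therefore
  scores the Mann–Whitney battery.

No multiple-testing correction is applied by default (a Benjamini–Hochberg
flag exists); α = 0.05 throughout.

## Classification

Features whose grouped-task ROC differs from chance (Hanley–McNeil
p < 0.05) in the rest, task or difference scope form the channel feature
matrix (scope subsets support rest-only / task-only / diff-only models).
Cross-validation is leave-one-hippocampus-out: all channels of one
hippocampus are held out per fold. Strictly inside each training fold the
pipeline imputes missing values by the median, standardizes, decorrelates
with PCA (all components retained) and fits an SVM with Platt-style sigmoid
calibration for channel probabilities. A per-fold ROC is undefined when the
held-out fold contains a single hippocampus (one class), so the reported
ROC/AUC pools the held-out probabilities across folds — the only
well-defined reading of a cross-validated mean ROC under this fold design.
A hippocampus is called epileptic when the mean probability of its channels
exceeds 0.5. Grid search spans linear and RBF kernels over
C, γ ∈ {10⁻³…10²} with one zoom level (×10^±0.5) around the best cell;
ties break toward smaller C, then linear before RBF. Determinism: all
stochastic components take the fold's seed; repeated runs give identical
reports.

## Synthetic cohort generator

The generator emulates the statistical structure of interictal hippocampal
iEEG across the four cells (EH/NEH × rest/task). Defaults for every cell
are the published per-channel feature means (rates, amplitudes,
frequencies, durations, IED statistics, correlations, relative entropies);
they define the study conditions and are not tuned per experiment.

* **Background**: 1/f^β colored noise, β = 1.5, SD 50 µV — a typical
  interictal broadband spectrum and amplitude scale for hippocampal depth
  contacts.
* **Coupling**: per electrode and band, channels mix a shared band-limited
  component with private ones, `x = √c·s + √(1−c)·n`, so the pair
  correlation of the band signals equals the coupling target c. Band
  components are renormalized to the deterministic in-band SD of the
  expected spectrum before mixing (per-realization normalization of
  colored noise is dominated by a handful of low-frequency bins and would
  otherwise scatter in-band variances by tens of percent).
* **Relative-entropy contrast**: each channel's band component is scaled by
  a constant factor that alternates in sign along the electrode, so every
  adjacent pair's amplitude distributions diverge by a fixed log-SD
  offset δ. The offset is read from a numeric calibration table of the
  symmetrized 10-bin histogram KL divergence between 1-s Gaussian windows
  (REN ≈ 0.009 + 0.9 δ² over the working range), so the measured
  relative entropy lands at the cell's target. The factors leave the
  window correlation at the coupling target, the detector's
  statistical-window normalization absorbs them, and injected event
  amplitudes are co-scaled so reported amplitude z is unaffected.
* **Events**: counts are Poisson with mean rate × duration/600 s, scaled
  by a per-hippocampus log-normal random effect (σ = 0.15) shared across
  conditions. HFO bursts are Tukey(0.5)-tapered sinusoids; spikes are
  Gaussian-derivative biphasic transients of 40 ms width (smooth spectrum,
  so the detector sees them as one floor-touching blob and discards them,
  as intended), amplitude floored at 100 µV. Events place uniformly with a
  one-duration guard margin; overlaps are allowed and kept distinct in the
  truth record.
* **Amplitude calibration**: HFO amplitudes are specified in detector
  z units. A calibrator maps target z to µV semi-analytically (band
  envelope statistics from a background probe, exact unit-burst peak
  response), then corrects the map by the median detected/requested ratio
  over probe injections — the max-over-overlapping-bands readout inflates
  reported z by a roughly constant factor (~1.3–1.7), an extreme-value
  effect the analytic model cannot capture. The correction is
  multiplicative rather than affine: a ratio preserves the relative
  differences between weak amplitude targets, where an additive offset
  would map distinct targets onto nearly identical injections and erase
  group contrasts. Requested amplitudes are floored at 0.5 envelope SDs —
  weak targets stay genuinely weak and may go undetected, which is the
  correct behaviour for a thresholding detector. A closed-form load
  correction additionally scales requests by √(1 + duty·0.55·z²) per
  cell, compensating the envelope-SD inflation caused by the cell's own
  event load; an optional probe-based per-cell refinement
  (``BurstCalibrator.calibrate_cells``) exists but is off by default.
* **Durations**: the duration parameters are detector-visible spans (the
  published duration features are detector measurements). The injected
  burst is longer by the inverse of the taper fraction above threshold at
  the event's amplitude, times a probe-estimated detected/visible ratio
  interpolated in 1/z. Event-level draws: frequency and duration from the
  cell's normal distributions truncated to valid ranges, amplitude
  z ~ N(cell mean, 1.2) floored at 3.5 (sub-threshold events are
  undetectable by definition and would only corrupt recovery statistics).

**What the generator does not emulate**: spike-and-wave morphology
variability, task-evoked potentials, sleep stages, seizures, line noise,
electrode artifacts, or any propagation structure between hippocampi.
Passing the validation experiments therefore shows that the pipeline
measures what the generator injects — rates, amplitudes, spectral content,
coupling and distributional divergence — faithfully and without leakage; it
does not certify performance on clinical recordings.

## Validation experiments and problem sizes

All experiments run at 2 kHz (valid for the 800 Hz ceiling) with sizes
chosen to keep a complete run on one CPU in minutes:

* **Injection recovery**: 20 ten-minute channels of 1/f background with
  EH-rest-parameter bursts (z ≥ 3.5, visible span ≥ 6 cycles); sensitivity,
  median frequency error (in band widths) and median duration error.
* **Noise false positives**: detected R+FR rate on pure background.
* **Type-I calibration**: 18 null cohorts (EH ≡ NEH generatively, 8+8
  hippocampi × 2 contacts, 30-s segments, no shared hippocampus random
  effect): 504 Mann–Whitney EH-vs-NEH tests. Event-derived features are
  tested per channel; connectivity features — which both contacts of a
  pair share — are tested on hippocampus medians, so every test's
  sampling units are independent and the nominal level is meaningful
  (channel-level tests on clustered channels are anti-conservative, a
  caveat that applies equally to multi-contact clinical data). The
  classifier's permutation null randomly permutes the channel label
  vector of a 16+16-hippocampus × 3-contact default-parameter cohort 20
  times through the leave-one-hippocampus-out SVM and reports the
  averaged pooled AUC. Pooled cross-validated AUC carries a pessimistic
  bias under the null — every sample is scored by a model trained on a
  set slightly depleted of its own class, and with uninformative inputs
  the Platt calibration collapses toward the training class fraction,
  which anti-correlates with the held-out labels — so the permutation
  cohort is deliberately larger than the test cohorts (the bias shrinks
  roughly as one over the channel count) and the permutation is applied
  to channel labels (group-level permutation would leave every held-out
  fold single-class and maximally exposed to that collapse).
* **Direction recovery**: 50 cohorts (2+2 hippocampi × 2 contacts, 45-s
  segments) at the default parameters; the pooled mean difference of each
  of the 44 contrasts reported as significant must carry the published
  sign.
* **Classification**: one 6+6-hippocampus cohort through feature
  selection, grid search and leave-one-hippocampus-out evaluation.

## Known limitations

* Detected dominant frequency retains a ~+10 % multiplicative bias from
  band overlap even with the centroid estimator; group contrasts survive
  because the bias is common to all cells.
* Near the detection floor (z ≈ 4–5) sensitivity falls below one, so
  measured amplitude means of weak-event groups are truncated upward
  relative to their generative targets; contrasts keep their sign but are
  compressed.
* The IED amplitude feature is peak-to-trough while the injected template
  amplitude specifies the single-lobe peak, so measured spike amplitudes
  run roughly 1.9× the generative parameter; group contrasts are
  unaffected.
* The Hanley–McNeil variance at the observed AUC is anti-conservative for
  small samples (see above); feature selection with it errs toward
  including marginal features, which the cross-validated evaluation then
  adjudicates.
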