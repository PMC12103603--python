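# Methods

This note documents the models, parameter choices and numerical conventions
behind `prosovoice`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and contours

**Framing.** Analysis frames are Hann-windowed, 20 ms long with a 4 ms hop,
half-open `[t, t + frame_len)`, trailing partial frames zero-padded. The
hop must subdivide the shortest smoothing span (20 ms); 4 ms gives five
frames inside it. Frame powers are normalised so bin powers sum to the
windowed frame's mean square (a discrete Parseval convention that makes the
spectrogram testable against a time-domain oracle).

**Loudness.** Per frame, bin powers are aggregated into the 24 Bark
critical bands (standard edge table, clipped to Nyquist) and compressed
with the stationary specific-loudness power law N′_b = (E_b/E_ref)^0.23,
then summed. Spread of masking and temporal post-masking are deliberately
omitted: the downstream features use contour *shape*, which the compressive
power law already captures, and a full ISO 532-B model can be swapped in
via the `band_loudness` hook. E_ref is fixed so a full-scale 1 kHz sine's
band maps to specific loudness 40. Absolute level calibration (phon) is
unavailable for the kind of recordings modelled, and every fixed reference
yields the same features up to a common monotone rescaling, so the choice
is inconsequential; the unit is reported as *relative* sone.

**F0.** A YIN-style tracker: per frame the cumulative-mean-normalised
difference function over lags [sr/fmax, sr/fmin] (defaults 60–400 Hz,
40 ms window) is minimised, with parabolic refinement of the lag; frames
with minimum CMNDF above the voicing threshold 0.15 (the conventional YIN
operating point) are unvoiced. Voiced F0 is expressed in octaves
log2(F0/100). Unvoiced gaps ≤ 0.25 s are bridged by linear interpolation
so phrase-scale smoothing can cross them — the voicing mask stays False and
statistics ignore the interpolated frames — while longer gaps are left NaN
and split the contour into segments. The frame length, hop and tracker
choice are reconstructions: the analysis this package models does not state
them.

## Multi-timescale features

**Span grid.** Three interleaved doubling chains {20, 25.2, 31.5} ms × 2^k,
k = 0..7, give 24 spans from 0.020 s to 4.032 s and contain every span
value the modelled analysis names (0.020, ≈0.101, 0.252, 4.032 s). The
grid stores nominal durations; the moving-average window is the nearest odd
number of hops (so 4.032 s becomes a 1007-frame window). A custom grid can
be passed through `ExtractionConfig`.

**Smoothing and derivatives.** Centred moving average per finite segment
with truncated windows at the edges (a window longer than its segment
degenerates to the segment mean); first derivative by central differences,
one-sided at segment ends, in units per second.

**Span-matched resampling.** Before statistics, each smoothed contour is
decimated to half its window length. A contour averaged over seconds is
massively oversampled at 4 ms, and frame-resolution statistics on it —
especially curvature and peak counts — would mostly measure the moving
average's stop-band residue rather than structure at the span's own time
scale, making every span an alias of the shortest ones. Half-window
sampling retains the passband content.

**Statistics.** On each smoothed contour and its derivative: mean, sample
SD, min, max, the 5/25/50/75/95% quantiles (linear interpolation), interior
strict peak and valley counts, mean peak prominence, mean amplitude between
consecutive extrema, extrema per second, and mean |second central
difference|/hop². Statistics undefined for a given input (SD of one frame,
prominence with no peak) are NaN, i.e. explicit missing values. The full
set applies to both layers for uniformity. With 2 tasks × 2 signals × 24
spans × 2 layers × 15 statistics the vector has 2 880 named features; the
original analysis reports a different raw count produced by a proprietary
curve-fitting step that is out of scope here, replaced by this documented
statistics set.

**Filtering.** Columns with variance below 2.2e-16 or fewer than 100
distinct values are dropped (the thresholds of the modelled analysis;
`min_unique` scales down for desk-scale cohorts, where 100 distinct values
may exceed the row count). Counting-type features (peak counts at long
spans) are the usual casualties.

## Cohort machinery

Exclusions run in two recording-level stages — technical/surplus flags
first, then drug-screen-positive participants, subclinical participants and
severe-cold recordings — followed by dropping excluded-group or
recording-less participants. Multi-flagged records get one primary reason
under the priority drug > technical > subclinical > cold, which makes the
reported counts well-defined; the reference manifest has no overlaps, so
the priority never has to fire there. The age-band split places exactly
32.0 years in the older band (the published split is boundary-silent; a
convention had to be fixed). Capping keeps the first three recordings by
visit index with recording id as tie-break.

## Learning

Random forests use the tree counts of the modelled analysis (500
classification, 100 regression) and otherwise the conventional defaults:
√p candidate features per split for classification, p/3 for regression,
unlimited depth, bootstrap on. Folds are label-stratified (target-quintile
stratified for regression); speaker-stratified mode keeps all recordings of
a participant in one fold and asserts that property every run. Per fold,
confounds are removed by OLS fitted on training rows only and applied to
both partitions, and missing features are imputed with training-fold
medians. Metrics are computed per repetition from the pooled held-out
predictions (AUC; precision/recall/F1 at probability 0.5 — the threshold
behind the modelled analysis's table is unstated, so 0.5 is a documented
assumption) and averaged over repetitions; the per-repetition series feeds
the corrected t-test. One master seed spawns per-repeat fold seeds and
per-fit forest seeds via `numpy.random.SeedSequence`, so results are
bit-reproducible.

OOB permutation importance grows its own bagged ensemble (explicit
bootstrap indices around `DecisionTreeClassifier`) because scikit-learn
exposes neither OOB indices nor OOB permutation importance publicly. Per
tree and per feature the OOB misclassification increase after permuting the
feature's OOB values is recorded — features a tree never splits on
contribute exactly zero — and importance is the mean increase divided by
its SD over trees, ties broken by feature name.

## Statistics

The corrected resampled t-test inflates the variance of the per-repetition
differences by n_test/n_train (1/9 for 10-fold), with df = J − 1 and
two-sided p. Degenerate inputs follow explicit conventions: zero variance
with zero mean gives t = 0, p = 1; zero variance with nonzero mean gives
±∞ with a warning. J is the number of entries in the metric series
(per-repetition by default; per-fold series can be passed just as well —
the appropriate unit is a judgement call the caller makes). Levene's test
is the classical mean-centred variant (the modelled analysis says only
"Levene's test"); median-centring is available, and a degenerate case with
no between-group spread in the absolute deviations returns W = 0, p = 1.

## Synthetic data: what it emulates, and what it does not

**Waveforms.** Voiced stretches are sums of the first 10 harmonics with
1/k roll-off (anti-aliased by capping harmonics at 0.45·sr), following
F0(t) = f0_base · 2^(drift + micro), with an envelope = base level ×
syllable modulation (≈4.5 Hz) × phrase modulation (0.2 Hz) × (1 + micro),
gated by a voiced/pause pattern and overlaid with white noise scaled by
`hnr_noise`. Glottal-pulse modelling was rejected as unnecessary: the
prosodic features see only the F0 trajectory and the envelope. Micro
components are *high-passed* noise (white minus its 0.3 s moving average):
the parameters mean short-timescale fluctuation, and slower structure is
the province of the modulation terms — without the high-pass, micro
variance leaks into phrase-level spans and every time scale becomes an
equally good group marker, which would make time-scale localisation
untestable. Peak samples stay within ±1 by construction at the default
level (0.3), with a deterministic rescale as a guard.

**Participants.** Symptom scores target the published group summaries
(clinical-interview total 40.0 ± 8.3 ADHD, 5.2 ± 4.4 HC, 23.3 ± 12.2 PC,
35.9 ± 11.6 excluded; subtype-specific hyperactivity 2.8 ± 1.6 ATT vs
7.0 ± 1.1 COM). Draws use moment-matched truncated normals: the underlying
(μ, σ) are solved so the truncated distribution reproduces the printed
moments — naive truncation at the printed parameters would, e.g., raise the
HC mean by about one point. Where the printed moments are infeasible for a
truncated normal (HC subscales with SD > mean near the floor), a censored
normal at the printed parameters is used instead. The 22 interview items
(0–3 each, total 0–66) are decomposed from the total by proportional
assignment with clipping, since only totals and subscale summaries are
published. Confound structure: sex sets the F0 register (male ≈115 Hz,
female ≈210 Hz), age raises the additive-noise floor linearly (a hoarseness
analogue), education nudges F0 drift. Severity θ = (total − 5.2)/6.64
(healthy-control mean, ADHD/HC pooled SD) scales `loud_micro_sd` and
`f0_micro_sd` by max(1 + g·θ, 0.1); the gain g defaults to 0.5 — the
modelled analysis reports loudness effects but no effect sizes, so g is a
config knob, not an estimate.

**The null and the confounds.** With g = 0 voice parameters are independent
of group, but the default config keeps group-specific sex ratios and
demographics, so a classifier could still find confound signal if
residualization failed — which is exactly what the null AUC check verifies.
The strict invariant "identical VoiceParams distributions across groups"
holds only with balanced demographics (`balanced_confounds=True`), which is
how the property test verifies it; each scalar draw consumes exactly one
uniform so matched seeds align streams across groups.

**What passing does not show.** The generator's effect channel is the one
the features were designed for; recovery therefore validates the pipeline's
plumbing (no leakage, correct localisation, calibrated nulls), not the
clinical effect size, and says nothing about phonetic realism,
room/channel acoustics, or whether real ADHD voices differ this way.

## Experiment scales

Desk-scale experiments use 60 + 60 speakers (50 + 50 for importance), one
recording each of 10 s free speech plus two 3 s counting trials, 10-fold
cross-validation with 10 repetitions, and the study-shaped defaults
elsewhere; the t-test calibration uses 500 null replicates of J = 100
series. These sizes are the package's reference desk-scale conditions,
chosen so the full validation runs comfortably on a single CPU while
keeping the metrics' Monte-Carlo noise well inside the asserted bands
(repeat-count stability of the pooled AUC is itself a tested property).

## Known limitations

- The loudness model is the power-law core of Zwicker's account, not a
  standards-grade implementation (no masking terms, no phon calibration).
- The proprietary curve-fitting feature step of the modelled analysis is
  replaced by a documented statistics set; raw feature counts differ.
- Counting trials are concatenated before extraction (pooling vs averaging
  is unstated in the modelled analysis).
- The F0 tracker is a plain CMNDF implementation without octave-jump
  post-processing; it is validated on clean synthetic material, not on
  noisy field recordings.
- Synthetic waveforms are not intelligible speech and carry no linguistic
  content by design.
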