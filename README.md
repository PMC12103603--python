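# prosovoice

Multi-timescale prosodic voice features and confound-aware random-forest
phenotyping for adult ADHD, exercised end-to-end on a synthetic cohort.

## The problem

Adults with ADHD show subtle paralinguistic differences — poorly modulated
loudness, altered pitch dynamics — that brief speech tasks (about 2 min of
free speech plus counting from one to ten) can capture. This package
implements the full analysis chain for studying that signal, for researchers
in digital phenotyping who want a tested, reproducible reference
implementation:

1. **Contours.** Each recording is reduced to a loudness contour in relative
   sone (short-time power spectrum → 24 Bark critical bands → Zwicker's
   specific-loudness power law N′_b = (E_b/E_ref)^0.23, summed over bands)
   and a speech-melody contour log2(F0/100 Hz) tracked with a YIN-style
   cumulative-mean-normalised difference function.
2. **Multi-timescale features.** Every contour is smoothed over 24 time
   spans from 0.020 s (micro-prosody) to 4.032 s (phrase relations), each
   smoothed contour and its first derivative are summarised by 15 statistics
   (location, spread, quantiles, peaks/valleys and their amplitude
   relations, curvature), giving 2 880 named features per recording, then
   filtered for near-zero variance and low cardinality.
3. **Learning.** Random-forest classification (500 trees) and regression
   (100 trees) under stratified 10-fold cross-validation repeated up to 100
   times, with sex, age and education regressed out of every feature
   *inside* each training fold (no leakage), plus out-of-bag permutation
   importance.
4. **Inference.** Fisher r-to-z, the Nadeau–Bengio corrected resampled
   t-test t = d̄ / √(σ̂²(1/J + n_test/n_train)) for comparing
   cross-validated metric series, and Levene's variance test.

Real clinical recordings of this kind are proprietary, so the package ships
a first-class synthetic generator: speech-like waveforms (harmonic voiced
stretches following an F0 trajectory, syllable/phrase amplitude modulation,
pauses, noise) and a cohort manifest shaped like the modelled study —
387 ADHD / 204 healthy / 100 psychiatric-control / 76 excluded participants,
1–3 recordings each, published symptom-score distributions, and the full
recruitment/exclusion flow (1029 → 1005 → 920 recordings). A latent
severity scales short-timescale loudness/F0 variability by (1 + g·θ); g = 0
is an exact null.

## Worked example

```python
from prosovoice import (CVConfig, cv_classify, filter_features,
                        generate_cohort)
from prosovoice.pipeline import extract_cohort_features
from prosovoice.synthetic_voice import CohortConfig

cfg = CohortConfig(n_adhd=20, n_hc=20, n_pc=0, n_excluded=0,
                   effect_gain_loud=0.5, effect_gain_f0=0.5,
                   visit_probs=(1.0, 0.0, 0.0),
                   free_speech_duration=8.0, counting_duration=3.0)
manifest = generate_cohort(cfg, seed=5)
fm = extract_cohort_features(manifest, master_seed=5)
filtered, _ = filter_features(fm, min_unique=30)
labels = fm.meta["group"].eq("ADHD").to_numpy().astype(int)
result = cv_classify(filtered, labels,
                     CVConfig(n_folds=5, n_repeats=3, n_trees_clf=200, seed=5))
print(result.pooled["auc"])
```

Running this (it is `examples/04_classification_recovery.py`) prints

```
gain g=0.5: pooled AUC = 0.988 over 40 recordings
gain g=0.0: pooled AUC = 0.539 over 40 recordings
```

— with the severity effect injected the cross-validated forest separates the
groups almost perfectly; with the gain at zero the identical pipeline sits
at chance, showing the signal comes from the injected prosodic effect and
not from the (still present, but residualized) sex/age/education confounds.
The other scripts in `examples/` walk through waveform synthesis, contour
and feature extraction, the exclusion flow, severity regression and the
statistical tests, each printing the numbers it computes.

A thin CLI wraps the same pipeline for shell use:

```bash
prosovoice fixture --out runs/fixture      # the reference exclusion flow
prosovoice run --out runs/demo --seed 1 --arm adhd_vs_hc --repeats 5
```

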