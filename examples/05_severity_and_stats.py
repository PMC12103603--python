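"""Severity regression and the package's statistical toolkit.

Regresses the clinical-interview total score on the voice features of a
small synthetic cohort (random-forest regression, pooled Pearson r and
MAE), compares two per-repeat metric series with the corrected resampled
t-test, and runs Levene's test on the inattention vs hyperactivity
subscales of a sampled ADHD group.
"""

import numpy as np

from prosovoice import CVConfig, cv_regress, filter_features, generate_cohort, levene_test, nb_corrected_ttest
from prosovoice.pipeline import extract_cohort_features
from prosovoice.synthetic_voice import CohortConfig, sample_participant

cfg = CohortConfig(
    n_adhd=18, n_hc=18, n_pc=0, n_excluded=0,
    visit_probs=(1.0, 0.0, 0.0),
    free_speech_duration=8.0, counting_duration=3.0,
    technical_recording_rate=0.0, severe_cold_rate=0.0,
)
manifest = generate_cohort(cfg, seed=6)
fm = extract_cohort_features(manifest, master_seed=6)
filtered, _ = filter_features(fm, min_unique=30)
target = fm.meta["adhd_dc_total"].to_numpy(dtype=float)

result = cv_regress(filtered, target, CVConfig(n_folds=6, n_repeats=4,
                                               n_trees_reg=100, seed=6))
print(f"severity regression: pooled r = {result.pooled['r']:.2f}, "
      f"MAE = {result.pooled['mae']:.1f} points on the 0-66 scale")

null = cv_regress(filtered, np.random.default_rng(6).permutation(target),
                  CVConfig(n_folds=6, n_repeats=4, n_trees_reg=100, seed=7))
test = nb_corrected_ttest(result.metric_series("r"), null.metric_series("r"))
print(f"corrected resampled t-test vs permuted target: "
      f"t = {test.statistic:.2f}, df = {test.df}, p = {test.p:.3f}")

adhd = [sample_participant("ADHD", seed=s)[0] for s in range(200)]
inatt = [p.inattention for p in adhd]
hyper = [p.hyperactivity for p in adhd]
lev = levene_test(inatt, hyper)
print(f"Levene inattention vs hyperactivity (ADHD group): "
      f"W = {lev.statistic:.1f}, p = {lev.p:.2g} "
      f"(SDs {np.std(inatt):.2f} vs {np.std(hyper):.2f})")
print("The hyperactivity subscale mixes two subtypes and so carries the "
      "larger variance, which Levene's test flags.")
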