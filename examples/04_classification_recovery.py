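"""Detect an injected prosodic effect with the cross-validated forest.

Generates a small ADHD-like vs healthy-control cohort in which clinical
severity scales the short-timescale loudness/F0 variability (gain g = 0.5),
extracts features, removes the sex/age/education confounds fold-
consistently, and reports the pooled AUC; then repeats with g = 0 (an exact
null) where the AUC must fall to chance.  Runs a couple of minutes on one
CPU at this reduced scale.
"""

from prosovoice import CVConfig, cv_classify, filter_features, generate_cohort
from prosovoice.pipeline import extract_cohort_features
from prosovoice.synthetic_voice import CohortConfig

for gain in (0.5, 0.0):
    cfg = CohortConfig(
        n_adhd=20, n_hc=20, n_pc=0, n_excluded=0,
        effect_gain_loud=gain, effect_gain_f0=gain,
        visit_probs=(1.0, 0.0, 0.0),
        free_speech_duration=8.0, counting_duration=3.0,
        technical_recording_rate=0.0, severe_cold_rate=0.0,
    )
    manifest = generate_cohort(cfg, seed=5)
    fm = extract_cohort_features(manifest, master_seed=5)
    filtered, _ = filter_features(fm, min_unique=30)
    labels = fm.meta["group"].eq("ADHD").to_numpy().astype(int)
    result = cv_classify(filtered, labels,
                         CVConfig(n_folds=5, n_repeats=3, n_trees_clf=200, seed=5))
    print(f"gain g={gain}: pooled AUC = {result.pooled['auc']:.3f} "
          f"over {len(labels)} recordings")

print("\nWith the effect injected the classifier separates the groups well "
      "above chance; with g=0 the same pipeline sits near AUC 0.5, showing "
      "the signal comes from the injected prosodic effect, not from "
      "confounds or leakage.")
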