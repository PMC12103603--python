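"""Canned synthetic-cohort experiments.

These bundle the package's standard validation experiments at desk scale:
effect recovery and null calibration of the classifier, confound-leak
safety, time-scale localisation of feature importance, and the calibration
of the corrected resampled t-test.  The experiment sizes (60 + 60 speakers,
10 s free speech + two 3 s counting trials, 10-fold cross-validation with
10 repetitions) are the package's reference desk-scale conditions; group
sizes, symptom distributions and exclusion rates inside the generator keep
their study-shaped defaults.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Tuple

import numpy as np

from .ml_pipeline import CVConfig, cv_classify, oob_importance
from .multiscale import filter_features, parse_feature_name
from .pipeline import extract_cohort_features
from .stats import MetricSeries, nb_corrected_ttest
from .synthetic_voice import CohortConfig, generate_cohort

__all__ = [
    "desk_scale_cohort_config",
    "effect_recovery_auc",
    "confound_safety_aucs",
    "importance_recovery",
    "nb_type1_rate",
]


def desk_scale_cohort_config(
    gain_loud: float = 0.5,
    gain_f0: float = 0.5,
    n_per_group: int = 60,
) -> CohortConfig:
    """ADHD-like vs HC-like cohort at desk scale: one recording each,
    10 s free speech and two 3 s counting trials."""
    return CohortConfig(
        n_adhd=n_per_group, n_hc=n_per_group, n_pc=0, n_excluded=0,
        effect_gain_loud=gain_loud, effect_gain_f0=gain_f0,
        visit_probs=(1.0, 0.0, 0.0),
        free_speech_duration=10.0, counting_duration=3.0,
        technical_recording_rate=0.0, severe_cold_rate=0.0,
    )


def _cohort_matrix(cfg: CohortConfig, seed: int):
    manifest = generate_cohort(cfg, seed)
    fm = extract_cohort_features(manifest, master_seed=seed)
    filtered, _ = filter_features(fm, min_unique=100)
    labels = fm.meta["group"].eq("ADHD").to_numpy().astype(int)
    return filtered, labels


def effect_recovery_auc(
    gain: float, seed: int, n_per_group: int = 60, n_repeats: int = 10
) -> Tuple[float, int]:
    """Pooled AUC of the ADHD-like vs HC-like contrast at effect gain g.

    ``gain = 0`` is the exact null (voice parameters independent of group);
    the default confound structure stays in place and is removed by
    fold-consistent residualization.
    """
    cfg = desk_scale_cohort_config(gain, gain, n_per_group)
    filtered, labels = _cohort_matrix(cfg, seed)
    res = cv_classify(filtered, labels, CVConfig(n_repeats=n_repeats, seed=seed))
    return res.pooled["auc"], len(labels)


def confound_safety_aucs(
    seed: int, n: int = 100, n_repeats: int = 5
) -> Tuple[float, float, int]:
    """AUC with and without residualization when the label IS a confound.

    Builds a tabular fixture whose features carry only confound signal and
    whose labels are a deterministic function of that confound; a leak-free
    pipeline must fall to chance once the confound is regressed out.
    """
    import pandas as pd

    from .multiscale import FeatureMatrix

    rng = np.random.default_rng(seed)
    conf = rng.standard_normal(n)
    labels = (conf > np.median(conf)).astype(int)
    X = np.outer(conf, rng.uniform(0.5, 1.5, 30)) + rng.normal(0, 0.1, (n, 30))
    fm = FeatureMatrix(
        pd.DataFrame(X, columns=[f"f{j}" for j in range(30)]),
        pd.DataFrame({"c": conf}),
    )
    base = CVConfig(n_repeats=n_repeats, n_trees_clf=100,
                    confound_names=("c",), seed=seed)
    with_removal = cv_classify(fm, labels, base)
    without = cv_classify(fm, labels, replace(base, remove_confounds=False))
    return with_removal.pooled["auc"], without.pooled["auc"], n


def importance_recovery(
    seed: int, n_per_group: int = 50, top_k: int = 10
) -> Tuple[int, int, int]:
    """Time-scale localisation of importance under a loudness-only effect.

    Injects the severity effect into loudness micro-variability only and
    counts how many of the top-``top_k`` OOB-importance features are
    loudness features at spans <= 0.252 s.  Returns (count, top_k, n rows).
    """
    cfg = desk_scale_cohort_config(gain_loud=0.5, gain_f0=0.0,
                                   n_per_group=n_per_group)
    filtered, labels = _cohort_matrix(cfg, seed)
    table = oob_importance(filtered, labels, CVConfig(seed=seed))
    infos = [parse_feature_name(f) for f in table.top(top_k)["feature"]]
    count = sum(1 for i in infos
                if i["signal"] == "loudness" and i["span_s"] <= 0.252)
    return count, top_k, len(labels)


def nb_type1_rate(
    seed: int, n_replicates: int = 500, series_len: int = 100,
    alpha: float = 0.05,
) -> Tuple[float, int]:
    """Empirical type-I error of the corrected resampled t-test.

    Two metric series per replicate are drawn from the same distribution
    (no true difference) with the 10-fold partition ratio
    n_test/n_train = 1/9; returns the fraction of replicates with p < alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = MetricSeries(rng.normal(0.7, 0.05, series_len), n_train=90, n_test=10)
        b = MetricSeries(rng.normal(0.7, 0.05, series_len), n_train=90, n_test=10)
        if nb_corrected_ttest(a, b).p < alpha:
            rejections += 1
    return rejections / n_replicates, n_replicates
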