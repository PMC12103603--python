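"""Cross-validated forests: residualization, fold machinery, metrics,
importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from prosovoice.ml_pipeline import (
    CVConfig,
    cv_classify,
    cv_regress,
    oob_importance,
    residualize_confounds,
)
from prosovoice.multiscale import FeatureMatrix


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg) with ties at 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestResidualize:
    def test_feature_equal_to_confound_gives_zero_residuals(self, rng):
        c = rng.standard_normal((20, 1))
        feat = c.copy()
        rtr, rte = residualize_confounds(feat[:15], feat[15:], c[:15], c[15:])
        assert np.abs(rtr).max() < 1e-10
        assert np.abs(rte).max() < 1e-8

    def test_zero_confounds_demean_with_training_mean(self, rng):
        X = rng.standard_normal((12, 3))
        C = np.zeros((12, 0))
        rtr, rte = residualize_confounds(X[:8], X[8:], C[:8], C[8:])
        assert np.allclose(rtr, X[:8] - X[:8].mean(axis=0))
        assert np.allclose(rte, X[8:] - X[:8].mean(axis=0))

    def test_orthogonal_feature_closed_form(self):
        """5-row example with a confound orthogonal to the feature."""
        c = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        feat = np.array([[1.0], [-1.0], [0.0], [-1.0], [1.0]])  # c . feat = 0
        rtr, _ = residualize_confounds(feat, feat, c, c)
        assert np.allclose(rtr, feat - feat.mean())

    def test_collinear_confounds_named_in_error(self, rng):
        c1 = rng.standard_normal((10, 1))
        C = np.hstack([c1, 2.0 * c1])
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="collinear"):
            residualize_confounds(X, X, C, C)

    def test_no_leakage_from_test_rows(self, rng):
        """Dropping the held-out rows leaves fitted coefficients unchanged."""
        X = rng.standard_normal((30, 4))
        C = rng.standard_normal((30, 2))
        r1, _ = residualize_confounds(X[:20], X[20:], C[:20], C[20:])
        r2, _ = residualize_confounds(X[:20], X[:1], C[:20], C[:1])
        assert np.array_equal(r1, r2)


def make_matrix(X, groups=None, confounds=None):
    Xdf = pd.DataFrame(np.asarray(X, float))
    Xdf.columns = [f"f{j}" for j in Xdf.columns]
    meta = pd.DataFrame(index=Xdf.index)
    if groups is not None:
        meta["participant_id"] = groups
    if confounds is not None:
        for k, v in confounds.items():
            meta[k] = v
    return FeatureMatrix(Xdf, meta)


class TestCvClassify:
    def test_separable_clouds_reach_auc_one(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 10)), rng.normal(8, 1, (20, 10))])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        res = cv_classify(pd.DataFrame(X), y,
                          CVConfig(n_repeats=2, n_trees_clf=100,
                                   remove_confounds=False, seed=0))
        assert res.pooled["auc"] == 1.0

    def test_permuted_labels_give_chance_auc(self, rng):
        X = rng.standard_normal((100, 20))
        y = rng.permutation(np.r_[np.zeros(50), np.ones(50)]).astype(int)
        res = cv_classify(pd.DataFrame(X), y,
                          CVConfig(n_repeats=10, n_trees_clf=100,
                                   remove_confounds=False, seed=1))
        assert 0.40 <= res.pooled["auc"] <= 0.60

    def test_auc_oracle_pair_counting(self):
        """{0.9, 0.35 | pos} vs {0.4, 0.8 | neg}: 2 of 4 concordant pairs."""
        scores = [0.9, 0.35, 0.4, 0.8]
        labels = [1, 1, 0, 0]
        assert brute_force_auc(scores, labels) == 0.5
        assert roc_auc_score(labels, scores) == 0.5

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=40)
        labels = (rng.uniform(size=40) < 0.4).astype(int)
        a1 = brute_force_auc(scores, labels)
        a2 = brute_force_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_speaker_stratification_keeps_participants_together(self, rng):
        n = 60
        X = rng.standard_normal((n, 5))
        groups = np.repeat([f"p{i}" for i in range(20)], 3)
        y = np.repeat((np.arange(20) % 2), 3)
        fm = make_matrix(X, groups=groups)
        res = cv_classify(fm, y, CVConfig(n_folds=5, n_repeats=3, n_trees_clf=20,
                                          stratify_speaker=True,
                                          remove_confounds=False, seed=2))
        for (rep, _), sub in res.predictions.groupby(["repeat", "fold"]):
            pass
        folds = res.predictions.copy()
        folds["pid"] = [groups[i] for i in folds["row_id"]]
        for rep, sub in folds.groupby("repeat"):
            spread = sub.groupby("pid")["fold"].nunique()
            assert (spread == 1).all()

    def test_confound_removal_protects_against_label_leak(self, rng):
        """Labels determined by a confound: residualization drops AUC to
        chance, skipping it leaves a confounded classifier."""
        n = 100
        conf = rng.standard_normal(n)
        y = (conf > np.median(conf)).astype(int)
        X = np.outer(conf, rng.uniform(0.5, 1.5, 30)) + rng.normal(0, 0.1, (n, 30))
        fm = make_matrix(X, confounds={"c": conf})
        base = CVConfig(n_repeats=3, n_trees_clf=100, confound_names=("c",), seed=3)
        with_removal = cv_classify(fm, y, base)
        import dataclasses
        without = cv_classify(fm, y, dataclasses.replace(base, remove_confounds=False))
        assert 0.4 <= with_removal.pooled["auc"] <= 0.6
        assert without.pooled["auc"] >= 0.9

    def test_pooled_auc_stable_in_repeat_count(self, rng):
        """Scaling repeats down from 100 to 10 moves the pooled AUC < 0.02."""
        X = np.vstack([rng.normal(0, 1, (40, 15)), rng.normal(0.8, 1, (40, 15))])
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        aucs = {}
        for reps in (10, 100):
            res = cv_classify(pd.DataFrame(X), y,
                              CVConfig(n_repeats=reps, n_trees_clf=100,
                                       remove_confounds=False, seed=9))
            aucs[reps] = res.pooled["auc"]
        assert abs(aucs[10] - aucs[100]) < 0.02

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError, match="classes"):
            cv_classify(X, np.zeros(10, int), CVConfig(n_repeats=1))


class TestCvRegress:
    def test_target_copied_into_feature_is_recovered(self, rng):
        n = 80
        target = rng.uniform(0, 10, n)
        X = rng.standard_normal((n, 10))
        X[:, 0] = target
        res = cv_regress(pd.DataFrame(X), target,
                         CVConfig(n_repeats=2, n_trees_reg=50,
                                  remove_confounds=False, seed=4))
        assert res.pooled["r"] > 0.9

    def test_independent_target_gives_null_r(self, rng):
        """Mean held-out r over independent null datasets stays near zero
        (a single dataset's chance correlation has SD ~ 1/sqrt(n))."""
        n = 150
        rs = []
        for k in range(4):
            res = cv_regress(pd.DataFrame(rng.standard_normal((n, 10))),
                             rng.uniform(0, 10, n),
                             CVConfig(n_repeats=3, n_trees_reg=50,
                                      remove_confounds=False, seed=5 + k))
            rs.append(res.pooled["r"])
        assert -0.15 <= np.mean(rs) <= 0.15

    def test_mae_hand_arithmetic(self):
        assert np.mean(np.abs(np.array([1, 2, 3]) - np.array([2, 2, 2]))) == pytest.approx(2 / 3)


class TestOOBImportance:
    def test_label_defining_feature_ranks_first(self, rng):
        n = 80
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        X = rng.standard_normal((n, 20))
        X[:, 7] = y + rng.normal(0, 0.05, n)
        table = oob_importance(pd.DataFrame(X, columns=[f"f{j}" for j in range(20)]),
                               y, CVConfig(n_trees_clf=200,
                                           remove_confounds=False, seed=6))
        assert table.table.iloc[0]["feature"] == "f7"

    def test_null_importances_centred_at_zero(self, rng):
        n = 60
        X = rng.standard_normal((n, 200))
        y = rng.permutation(np.r_[np.zeros(30), np.ones(30)]).astype(int)
        table = oob_importance(pd.DataFrame(X), y,
                               CVConfig(n_trees_clf=150,
                                        remove_confounds=False, seed=7))
        assert np.abs(table.table["importance"]).mean() < 0.5

    def test_ranks_unique_and_sorted(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 15)))
        y = (rng.uniform(size=40) < 0.5).astype(int)
        table = oob_importance(X, y, CVConfig(n_trees_clf=50,
                                              remove_confounds=False, seed=8)).table
        assert sorted(table["rank"]) == list(range(1, 16))
        assert (np.diff(table["importance"]) <= 1e-12).all()
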