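"""Random-forest classification and regression under repeated k-fold
cross-validation, with fold-consistent confound residualization, pooled
metrics, and out-of-bag permutation importance.

Confound handling follows the cross-validation-consistent recipe: for every
feature an ordinary-least-squares model ``feature ~ intercept + confounds``
is estimated on the training fold only and its prediction subtracted from
both partitions, so the forest never sees information that leaked from the
held-out rows.  Missing feature values are median-imputed with training-fold
medians for the same reason.

Metrics are computed per repetition from the pooled held-out predictions of
its folds (AUC, precision/recall/F1 at probability 0.5 for classification;
Pearson r and MAE for regression) and then averaged over repetitions; the
per-repetition series feeds the corrected resampled t-tests in
:mod:`prosovoice.stats`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .stats import MetricSeries, confusion_metrics

__all__ = ["CVConfig", "CVResult", "residualize_confounds", "cv_classify",
           "cv_regress", "oob_importance", "ImportanceTable"]

log = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """Cross-validation and forest settings.

    Tree counts follow the modelled analysis (500 for classification, 100
    for regression); all other forest hyperparameters are the conventional
    defaults — sqrt(p) candidate features per split for classification,
    p/3 for regression, unlimited depth, bootstrap resampling on.
    """

    n_folds: int = 10
    n_repeats: int = 100
    n_trees_clf: int = 500
    n_trees_reg: int = 100
    stratify_speaker: bool = False
    remove_confounds: bool = True
    confound_names: Tuple[str, ...] = ("sex", "age", "education")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_trees_clf < 1 or self.n_trees_reg < 1:
            raise ValueError("tree counts must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVResult:
    """Held-out predictions and metrics of a repeated-CV run."""

    predictions: pd.DataFrame        # columns: repeat, fold, row_id, score, y_true
    per_repeat: pd.DataFrame         # one metric row per (non-degenerate) repeat
    pooled: Dict[str, float]         # mean over repeats
    n_train: int                     # typical training-fold size
    n_test: int                      # typical held-out-fold size
    config: CVConfig
    flagged_repeats: List[int] = field(default_factory=list)

    def metric_series(self, metric: str) -> MetricSeries:
        """Per-repeat series of one metric, ready for the corrected t-test."""
        return MetricSeries(self.per_repeat[metric].to_numpy(),
                            n_train=self.n_train, n_test=self.n_test)

    def to_json(self, path=None) -> str:
        payload = {
            "pooled": self.pooled,
            "per_repeat": self.per_repeat.to_dict(orient="list"),
            "n_train": self.n_train, "n_test": self.n_test,
            "flagged_repeats": self.flagged_repeats,
            "config": self.config.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_confound_matrix(confounds: pd.DataFrame) -> np.ndarray:
    """Numeric confound matrix; binary sex labels become a 0/1 dummy."""
    cols = []
    for c in confounds.columns:
        col = confounds[c]
        if col.dtype == object or str(col.dtype) == "category":
            col = pd.factorize(col)[0]
        cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(confounds), 0))


def residualize_confounds(
    train_features: np.ndarray,
    test_features: np.ndarray,
    train_confounds: np.ndarray,
    test_confounds: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """OLS residuals of every feature on intercept + confounds.

    The regression is fitted on training rows only and applied to both
    partitions.  Raises if the design matrix (with intercept) is rank
    deficient, naming the offending columns.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    Ctr = np.asarray(train_confounds, dtype=float)
    Cte = np.asarray(test_confounds, dtype=float)
    n, q = Ctr.shape
    design_tr = np.column_stack([np.ones(n), Ctr])
    rank = np.linalg.matrix_rank(design_tr)
    if rank < q + 1:
        bad = []
        for j in range(q):
            sub = np.column_stack([np.ones(n), Ctr[:, : j + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(j)
        raise ValueError(f"confound matrix is rank deficient (collinear columns: {bad})")
    design_te = np.column_stack([np.ones(Cte.shape[0]), Cte])
    # one lstsq per feature block: solve for all features at once
    nan_tr = np.isnan(Xtr)
    if nan_tr.any():
        col_med = np.nanmedian(Xtr, axis=0)
        Xtr = np.where(nan_tr, col_med, Xtr)
        Xte = np.where(np.isnan(Xte), col_med, Xte)
    beta, *_ = np.linalg.lstsq(design_tr, Xtr, rcond=None)
    return Xtr - design_tr @ beta, Xte - design_te @ beta


def _impute_train_medians(Xtr: np.ndarray, Xte: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    Xtr = np.where(np.isnan(Xtr), med, Xtr)
    Xte = np.where(np.isnan(Xte), med, Xte)
    return Xtr, Xte


def _fold_iterator(y, groups, cfg: CVConfig, repeat_seed: int):
    if cfg.stratify_speaker:
        if groups is None:
            raise ValueError("speaker stratification needs participant ids")
        splitter = StratifiedGroupKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=repeat_seed)
        return splitter.split(np.zeros(len(y)), y, groups=groups)
    splitter = StratifiedKFold(
        n_splits=cfg.n_folds, shuffle=True, random_state=repeat_seed)
    return splitter.split(np.zeros(len(y)), y)


def _repeat_seeds(cfg: CVConfig, n: int) -> List[np.random.SeedSequence]:
    return np.random.SeedSequence(cfg.seed).spawn(n)


def _prepare_fold(X, confounds, train_idx, test_idx, cfg: CVConfig):
    Xtr, Xte = X[train_idx], X[test_idx]
    if cfg.remove_confounds and confounds is not None:
        Xtr, Xte = residualize_confounds(
            Xtr, Xte, confounds[train_idx], confounds[test_idx])
    return _impute_train_medians(Xtr, Xte)


def _run_cv(matrix, y: np.ndarray, cfg: CVConfig) -> CVResult:
    X, confounds, groups, row_ids = _unpack_matrix(matrix, cfg)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("classification needs at least 2 classes")

    pred_rows = []
    metric_rows = []
    flagged = []
    seeds = _repeat_seeds(cfg, cfg.n_repeats)
    for rep in range(cfg.n_repeats):
        rep_ss = seeds[rep]
        fold_seed = int(rep_ss.generate_state(1)[0] % (2**31 - 1))
        fit_seeds = rep_ss.spawn(cfg.n_folds)
        scores = np.full(len(y), np.nan)
        ok = True
        folds = list(_fold_iterator(y, groups, cfg, fold_seed))
        for k, (tr, te) in enumerate(folds):
            if np.unique(y[tr]).size < 2:
                log.warning("repeat %d fold %d has a single training class; "
                            "repeat excluded from pooling", rep, k)
                ok = False
                break
            Xtr, Xte = _prepare_fold(X, confounds, tr, te, cfg)
            fs = int(fit_seeds[k].generate_state(1)[0] % (2**31 - 1))
            model = RandomForestClassifier(
                n_estimators=cfg.n_trees_clf, max_features="sqrt",
                random_state=fs, n_jobs=1)
            model.fit(Xtr, y[tr])
            pos = list(model.classes_).index(1)
            scores[te] = model.predict_proba(Xte)[:, pos]
            for i in te:
                pred_rows.append((rep, k, row_ids[i], scores[i], y[i]))
        if not ok:
            flagged.append(rep)
            continue
        auc = float(roc_auc_score(y, scores))
        prec, rec, f1 = confusion_metrics((scores >= 0.5).astype(int), y)
        metric_rows.append({"repeat": rep, "auc": auc, "precision": prec,
                            "recall": rec, "f1": f1})

    per_repeat = pd.DataFrame(metric_rows)
    if per_repeat.empty:
        raise ValueError("every repeat was degenerate; no metrics available")
    pooled = {c: float(per_repeat[c].mean())
              for c in per_repeat.columns if c != "repeat"}
    n_test = int(round(len(y) / cfg.n_folds))
    return CVResult(
        predictions=pd.DataFrame(
            pred_rows, columns=["repeat", "fold", "row_id", "score", "y_true"]),
        per_repeat=per_repeat, pooled=pooled,
        n_train=len(y) - n_test, n_test=n_test,
        config=cfg, flagged_repeats=flagged,
    )


def _unpack_matrix(matrix, cfg: CVConfig):
    """Accept a FeatureMatrix or a plain DataFrame/array."""
    from .multiscale import FeatureMatrix

    groups = None
    confounds = None
    if isinstance(matrix, FeatureMatrix):
        X = matrix.features.to_numpy(dtype=float)
        row_ids = list(matrix.features.index)
        meta = matrix.meta
        if len(meta):
            if "participant_id" in meta.columns:
                groups = meta["participant_id"].to_numpy()
            have = [c for c in cfg.confound_names if c in meta.columns]
            if cfg.remove_confounds:
                missing = set(cfg.confound_names) - set(have)
                if missing:
                    raise ValueError(f"missing confound columns: {sorted(missing)}")
                confounds = _as_confound_matrix(meta[list(cfg.confound_names)])
    elif isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        row_ids = list(matrix.index)
    else:
        X = np.asarray(matrix, dtype=float)
        row_ids = list(range(X.shape[0]))
    if cfg.remove_confounds and confounds is None:
        # no metadata: nothing to residualize
        confounds = None
    return X, confounds, groups, row_ids


def cv_classify(matrix, labels, config: Optional[CVConfig] = None) -> CVResult:
    """Repeated, label-stratified k-fold random-forest classification.

    Per fold: optional confound residualization (training-fold fit),
    training-median imputation, forest fit, held-out class-1 probabilities.
    Per repeat: AUC from the pooled held-out scores plus precision, recall
    and F1 at probability threshold 0.5.  Repeats with a single-class
    training fold are flagged and excluded from pooling.
    """
    return _run_cv(matrix, labels, config or CVConfig())


def cv_regress(matrix, target, config: Optional[CVConfig] = None) -> CVResult:
    """Repeated k-fold random-forest regression (Pearson r and MAE).

    Fold machinery matches :func:`cv_classify`; stratification bins the
    continuous target into quintiles so folds share its distribution.
    """
    cfg = config or CVConfig()
    y = np.asarray(target, dtype=float)
    bins = np.quantile(y, [0.2, 0.4, 0.6, 0.8])
    strata = np.digitize(y, bins)
    return _run_cv_regression(matrix, y, strata, cfg)


def _run_cv_regression(matrix, y, strata, cfg):
    X, confounds, groups, row_ids = _unpack_matrix(matrix, cfg)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise ValueError("regression target needs at least 2 distinct values")
    pred_rows, metric_rows, flagged = [], [], []
    seeds = _repeat_seeds(cfg, cfg.n_repeats)
    for rep in range(cfg.n_repeats):
        rep_ss = seeds[rep]
        fold_seed = int(rep_ss.generate_state(1)[0] % (2**31 - 1))
        fit_seeds = rep_ss.spawn(cfg.n_folds)
        scores = np.full(len(y), np.nan)
        folds = list(_fold_iterator(strata, groups, cfg, fold_seed))
        for k, (tr, te) in enumerate(folds):
            Xtr, Xte = _prepare_fold(X, confounds, tr, te, cfg)
            fs = int(fit_seeds[k].generate_state(1)[0] % (2**31 - 1))
            model = RandomForestRegressor(
                n_estimators=cfg.n_trees_reg, max_features=1.0 / 3.0,
                random_state=fs, n_jobs=1)
            model.fit(Xtr, y[tr])
            scores[te] = model.predict(Xte)
            for i in te:
                pred_rows.append((rep, k, row_ids[i], scores[i], y[i]))
        mae = float(np.mean(np.abs(scores - y)))
        if np.std(scores) == 0 or np.std(y) == 0:
            log.warning("repeat %d: zero-variance predictions, r undefined", rep)
            flagged.append(rep)
            metric_rows.append({"repeat": rep, "r": np.nan, "mae": mae})
            continue
        r = float(np.corrcoef(y, scores)[0, 1])
        metric_rows.append({"repeat": rep, "r": r, "mae": mae})
    per_repeat = pd.DataFrame(metric_rows)
    pooled = {c: float(per_repeat[c].mean()) for c in per_repeat.columns if c != "repeat"}
    n_test = int(round(len(y) / cfg.n_folds))
    return CVResult(
        predictions=pd.DataFrame(
            pred_rows, columns=["repeat", "fold", "row_id", "score", "y_true"]),
        per_repeat=per_repeat, pooled=pooled,
        n_train=len(y) - n_test, n_test=n_test, config=cfg,
        flagged_repeats=flagged,
    )


@dataclass
class ImportanceTable:
    """Out-of-bag permutation importance, sorted descending."""

    table: pd.DataFrame  # columns: feature, importance, rank

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def oob_importance(matrix, labels, config: Optional[CVConfig] = None) -> ImportanceTable:
    """OOB permutation importance of a bagged classification forest.

    A forest of ``n_trees_clf`` trees is grown on explicit bootstrap samples
    of the full data.  For each tree and each feature the tree actually
    splits on, the feature's values are permuted within the tree's
    out-of-bag rows and the increase in OOB misclassification error is
    recorded (features a tree never uses contribute exactly zero).  The
    importance of a feature is its mean error increase over trees divided by
    the standard deviation over trees; ties in the sort are broken by
    feature name for determinism.
    """
    cfg = config or CVConfig()
    X, confounds, _groups, _ids = _unpack_matrix(matrix, cfg)
    y = np.asarray(labels)
    if cfg.remove_confounds and confounds is not None:
        X, _ = residualize_confounds(X, X, confounds, confounds)
    X, _ = _impute_train_medians(X, X)
    feature_names = (list(matrix.features.columns)
                     if hasattr(matrix, "features") else
                     list(matrix.columns) if isinstance(matrix, pd.DataFrame)
                     else [f"f{j}" for j in range(X.shape[1])])
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    deltas = np.zeros((cfg.n_trees_clf, p))
    for t in range(cfg.n_trees_clf):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X32[boot], y[boot])
        if oob.size < 2:
            continue
        Xo = X32[oob].copy()
        base_err = float(np.mean(tree.predict(Xo) != y[oob]))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[rng.permutation(oob.size)]
            perm_err = float(np.mean(tree.predict(Xo) != y[oob]))
            Xo[:, j] = saved
            deltas[t, j] = perm_err - base_err
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        importance = np.where(sd > 0, mean / sd, 0.0)
    table = pd.DataFrame({"feature": feature_names, "importance": importance})
    table = table.sort_values(["importance", "feature"],
                              ascending=[False, True]).reset_index(drop=True)
    table["rank"] = np.arange(1, p + 1)
    return ImportanceTable(table)
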