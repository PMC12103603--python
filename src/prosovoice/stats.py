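"""Inferential layer: Fisher r-to-z, the Nadeau–Bengio corrected resampled
t-test for cross-validated metric series, Levene's variance comparison, and
confusion-matrix metrics.

The Nadeau–Bengio correction addresses the optimism of a naive t-test on
per-fold (or per-repeat) cross-validation metrics: because training sets
overlap, the metric values are positively correlated and the usual variance
estimate is too small.  The corrected statistic inflates the variance by the
test/train partition ratio,

    t = dbar / sqrt( s2 * (1/J + n_test/n_train) ),   df = J - 1,

which is conservative under independence and approximately calibrated under
the overlap-induced correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "MetricSeries",
    "fisher_z",
    "fisher_z_inv",
    "nb_corrected_ttest",
    "levene_test",
    "confusion_metrics",
    "TestResult",
]


@dataclass
class MetricSeries:
    """Per-fold (or per-repeat) metric values with the fold partition sizes."""

    values: np.ndarray
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("a metric series needs at least 2 values")
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("partition sizes must be positive")

    @property
    def rho(self) -> float:
        """Variance-inflation ratio n_test/n_train."""
        return self.n_test / self.n_train


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p": self.p,
                "method": self.method}


def fisher_z(r: float) -> float:
    """Fisher r-to-z transform, z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("fisher_z requires |r| < 1")
    return math.atanh(r)


def fisher_z_inv(z: float) -> float:
    """Inverse of :func:`fisher_z` (tanh)."""
    return math.tanh(float(z))


def nb_corrected_ttest(
    series_a: MetricSeries,
    series_b: Optional[MetricSeries] = None,
) -> TestResult:
    """Nadeau–Bengio corrected resampled t-test.

    Paired when ``series_b`` is given (element-wise differences of two
    equal-length series from the same resampling plan), one-sample against 0
    otherwise.  Two-sided p from Student's t with J-1 degrees of freedom.
    """
    a = series_a.values
    if series_b is not None:
        b = series_b.values
        if b.size != a.size:
            raise ValueError("paired series must have equal length")
        d = a - b
    else:
        d = a
    j = d.size
    dbar = float(np.mean(d))
    s2 = float(np.var(d, ddof=1))
    rho = series_a.rho
    method = f"Nadeau-Bengio corrected t-test (J={j}, n_test/n_train={rho:.4g})"
    if s2 == 0.0:
        if dbar == 0.0:
            return TestResult(0.0, j - 1, 1.0, method)
        warnings.warn("zero variance with nonzero mean difference; t is infinite")
        return TestResult(math.copysign(math.inf, dbar), j - 1, 0.0, method)
    t = dbar / math.sqrt(s2 * (1.0 / j + rho))
    p = 2.0 * sps.t.sf(abs(t), df=j - 1)
    return TestResult(t, j - 1, p, method)


def levene_test(group_a, group_b, center: str = "mean") -> TestResult:
    """Levene's test for equality of variances between two groups.

    Classical (mean-centred) variant by default: a one-way ANOVA F on the
    absolute deviations from each group's mean; ``center='median'`` gives the
    Brown–Forsythe variant.  If the absolute deviations show no between-group
    spread at all, W = 0 and p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    centre = np.mean if center == "mean" else np.median
    da = np.abs(a - centre(a))
    db = np.abs(b - centre(b))
    grand = np.mean(np.concatenate([da, db]))
    ss_between = a.size * (np.mean(da) - grand) ** 2 + b.size * (np.mean(db) - grand) ** 2
    method = f"Levene ({center}-centred)"
    if ss_between <= 1e-300:
        return TestResult(0.0, (1, a.size + b.size - 2), 1.0, method)
    w, p = sps.levene(a, b, center=center)
    return TestResult(float(w), (1, a.size + b.size - 2), float(p), method)


def confusion_metrics(predicted, true) -> tuple[float, float, float]:
    """(precision, recall, F1) for binary labels with positive class 1.

    Zero-denominator metrics are reported as NaN (undefined), mirroring how
    a fold with no positive predictions yields an undefined precision.
    """
    yp = np.asarray(predicted).astype(int)
    yt = np.asarray(true).astype(int)
    if not (set(np.unique(yp)) <= {0, 1} and set(np.unique(yt)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((yp == 1) & (yt == 1)))
    fp = int(np.sum((yp == 1) & (yt == 0)))
    fn = int(np.sum((yp == 0) & (yt == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    if np.isnan(precision) or np.isnan(recall):
        f1 = np.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1
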