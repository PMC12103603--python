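"""Multi-timescale contour features.

Each base contour (loudness, log-F0) is smoothed over 24 time spans running
from 20 ms ("micro-prosodic" structure) to 4.032 s (phrase-level relations),
giving 24 contours per signal.  On every smoothed contour and on its first
derivative a fixed set of summary statistics is computed — location and
spread, quantiles, and slope-derived shape features (peaks, valleys, their
amplitude relations, curvature).  The assembled per-recording feature vector
follows the name schema::

    {signal}__{task}__span{NN}_{duration}s__{layer}__{stat}

e.g. ``loudness__free_speech__span12_0.252s__derivative__sd``.

The span grid is three interleaved doubling chains {20, 25.2, 31.5} ms × 2^k,
k = 0..7 — 24 values whose extremes and named members (0.020, ~0.101, 0.252,
4.032 s) match the analysis this package models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .audio_features import (
    Contour,
    DEFAULT_FRAME_HOP,
    DEFAULT_FRAME_LEN,
    f0_contour,
    loudness_contour,
    stft_frames,
)

__all__ = [
    "SpanGrid",
    "default_span_grid",
    "smooth",
    "derivative",
    "contour_stats",
    "STAT_NAMES",
    "ExtractionConfig",
    "extract_features",
    "feature_name",
    "parse_feature_name",
    "FeatureMatrix",
    "filter_features",
    "FilterReport",
    "FEATURES_PER_RECORDING",
]

#: Statistics computed on every (smoothed contour | derivative) layer.
STAT_NAMES = (
    "mean", "sd", "min", "max",
    "q05", "q25", "q50", "q75", "q95",
    "peak_count", "valley_count",
    "peak_prominence", "peak_valley_amp", "peak_valley_rate",
    "curvature",
)

TASKS = ("free_speech", "counting")
SIGNALS = ("loudness", "f0")
LAYERS = ("contour", "derivative")

#: Documented constant of this implementation:
#: 2 tasks x 2 signals x 24 spans x 2 layers x 15 statistics.
FEATURES_PER_RECORDING = 2 * 2 * 24 * 2 * len(STAT_NAMES)


@dataclass(frozen=True)
class SpanGrid:
    """24 smoothing spans in seconds, ascending."""

    spans: tuple  # nominal durations, s
    frame_hop: float

    def __post_init__(self) -> None:
        s = np.asarray(self.spans, dtype=float)
        if s.size != 24:
            raise ValueError("a span grid has exactly 24 spans")
        if np.any(np.diff(s) <= 0):
            raise ValueError("spans must be strictly increasing")

    def window_frames(self, span: float) -> int:
        """Nearest odd number of frame hops covering ``span`` (>= 1)."""
        return _odd_window(span, self.frame_hop)

    def __iter__(self):
        return iter(self.spans)

    def __len__(self) -> int:
        return len(self.spans)


def _odd_window(span: float, frame_hop: float) -> int:
    w = int(round(span / frame_hop))
    if w % 2 == 0:
        lo, hi = w - 1, w + 1
        w = lo if abs(lo * frame_hop - span) <= abs(hi * frame_hop - span) else hi
    return max(1, w)


def default_span_grid(frame_hop: float = DEFAULT_FRAME_HOP) -> SpanGrid:
    """Three interleaved doubling chains {20, 25.2, 31.5} ms x 2^0..7."""
    if abs(round(0.020 / frame_hop) - 0.020 / frame_hop) > 1e-6:
        raise ValueError("frame_hop must subdivide the 20 ms base span")
    bases_ms = (20.0, 25.2, 31.5)
    spans = sorted(b * 2.0**k / 1000.0 for b in bases_ms for k in range(8))
    return SpanGrid(tuple(spans), frame_hop)


def _finite_segments(values: np.ndarray) -> Iterable[slice]:
    """Contiguous runs of finite values."""
    finite = np.isfinite(values)
    n = values.size
    i = 0
    while i < n:
        if finite[i]:
            j = i
            while j < n and finite[j]:
                j += 1
            yield slice(i, j)
            i = j
        else:
            i += 1


def smooth(contour: Contour, span: float) -> Contour:
    """Centred moving average over an odd window of ``span`` seconds.

    Applied independently per finite segment; window edges shrink (truncate)
    at segment boundaries, so a window longer than the segment reduces the
    segment to its overall mean.  Non-finite frames (long unvoiced gaps)
    split segments and stay NaN.  The validity mask is passed through.
    """
    if span < contour.frame_hop - 1e-12:
        raise ValueError("span must be at least one frame hop")
    half = _odd_window(span, contour.frame_hop) // 2
    out = np.full_like(contour.values, np.nan, dtype=float)
    v = contour.values
    for seg in _finite_segments(v):
        s = v[seg]
        n = s.size
        cs = np.concatenate([[0.0], np.cumsum(s)])
        i = np.arange(n)
        lo = np.maximum(i - half, 0)
        hi = np.minimum(i + half + 1, n)
        out[seg] = (cs[hi] - cs[lo]) / (hi - lo)
    return Contour(out, contour.frame_hop, valid_mask=contour.valid_mask.copy())


def derivative(contour: Contour) -> Contour:
    """First derivative in units of value per second.

    Central differences on segment interiors, one-sided at segment ends;
    segments shorter than 2 frames become NaN.
    """
    v = contour.values
    out = np.full_like(v, np.nan, dtype=float)
    h = contour.frame_hop
    for seg in _finite_segments(v):
        s = v[seg]
        if s.size < 2:
            continue
        d = np.empty_like(s)
        d[1:-1] = (s[2:] - s[:-2]) / (2.0 * h)
        d[0] = (s[1] - s[0]) / h
        d[-1] = (s[-1] - s[-2]) / h
        out[seg] = d
    return Contour(out, contour.frame_hop, valid_mask=contour.valid_mask.copy())


def _valid_runs(contour: Contour) -> Iterable[np.ndarray]:
    """Contiguous runs of frames that are both valid and finite."""
    ok = contour.valid_mask & np.isfinite(contour.values)
    n = ok.size
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            yield contour.values[i:j]
            i = j
        else:
            i += 1


def contour_stats(contour: Contour) -> Dict[str, float]:
    """Summary statistics over valid frames.

    Location/spread/quantile statistics use all valid frames pooled; shape
    statistics (peaks = interior strict maxima, valleys = interior strict
    minima, prominence, peak-to-valley amplitude, curvature) are computed per
    contiguous valid run and aggregated.  Undefined statistics (SD on one
    frame, prominence with no peak, curvature on < 3 frames) are NaN.
    """
    runs = list(_valid_runs(contour))
    vals = np.concatenate(runs) if runs else np.array([])
    out = {k: np.nan for k in STAT_NAMES}
    if vals.size == 0:
        return out
    out["mean"] = float(np.mean(vals))
    out["sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
    out["min"] = float(np.min(vals))
    out["max"] = float(np.max(vals))
    for q, name in zip((5, 25, 50, 75, 95), ("q05", "q25", "q50", "q75", "q95")):
        out[name] = float(np.quantile(vals, q / 100.0))

    n_peaks = 0
    n_valleys = 0
    proms: list = []
    pv_amps: list = []
    curvs: list = []
    for s in runs:
        if s.size >= 3:
            pk, props = find_peaks(s, prominence=0)
            vl, _ = find_peaks(-s)
            n_peaks += pk.size
            n_valleys += vl.size
            proms.extend(props["prominences"].tolist())
            ext = np.sort(np.concatenate([pk, vl]))
            if ext.size >= 2:
                pv_amps.extend(np.abs(np.diff(s[ext])).tolist())
            second = s[2:] - 2 * s[1:-1] + s[:-2]
            curvs.extend(np.abs(second / contour.frame_hop**2).tolist())
    out["peak_count"] = float(n_peaks)
    out["valley_count"] = float(n_valleys)
    out["peak_prominence"] = float(np.mean(proms)) if proms else np.nan
    out["peak_valley_amp"] = float(np.mean(pv_amps)) if pv_amps else np.nan
    duration = vals.size * contour.frame_hop
    out["peak_valley_rate"] = float((n_peaks + n_valleys) / duration)
    out["curvature"] = float(np.mean(curvs)) if curvs else np.nan
    return out


def feature_name(signal: str, task: str, span_idx: int, span: float, layer: str, stat: str) -> str:
    return f"{signal}__{task}__span{span_idx:02d}_{span:g}s__{layer}__{stat}"


_NAME_RE = re.compile(
    r"^(?P<signal>\w+)__(?P<task>\w+)__span(?P<idx>\d+)_(?P<span>[\d.]+)s__"
    r"(?P<layer>\w+)__(?P<stat>\w+)$"
)


def parse_feature_name(name: str) -> Dict[str, object]:
    """Invert :func:`feature_name` → dict(signal, task, span_idx, span_s, layer, stat)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a feature name: {name!r}")
    return {
        "signal": m["signal"], "task": m["task"],
        "span_idx": int(m["idx"]), "span_s": float(m["span"]),
        "layer": m["layer"], "stat": m["stat"],
    }


@dataclass
class ExtractionConfig:
    """Frame and tracker settings for contour extraction."""

    sample_rate: float = 22050.0
    frame_len: float = DEFAULT_FRAME_LEN
    frame_hop: float = DEFAULT_FRAME_HOP
    f0_frame_len: float = 0.040
    fmin: float = 60.0
    fmax: float = 400.0
    voicing_threshold: float = 0.15
    span_grid: Optional[SpanGrid] = None

    def grid(self) -> SpanGrid:
        return self.span_grid or default_span_grid(self.frame_hop)


def decimate_contour(contour: Contour, step: int) -> Contour:
    """Every ``step``-th frame of a contour; frame hop scales accordingly.

    Used after smoothing: a contour averaged over a span is oversampled at
    the base hop, and statistics read at 4 ms resolution on a seconds-long
    moving average mostly measure smoothing residue.  Sampling at half the
    window (the span's natural rate) keeps the passband content.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    return Contour(contour.values[::step], contour.frame_hop * step,
                   valid_mask=contour.valid_mask[::step])


def _base_contours(waveform: np.ndarray, cfg: ExtractionConfig) -> Dict[str, Contour]:
    spec = stft_frames(waveform, cfg.sample_rate, cfg.frame_len, cfg.frame_hop)
    loud = loudness_contour(spec)
    f0 = f0_contour(
        waveform, cfg.sample_rate, cfg.f0_frame_len, cfg.frame_hop,
        cfg.fmin, cfg.fmax, cfg.voicing_threshold,
    )
    return {"loudness": loud, "f0": f0}


def extract_features(
    waveforms: Mapping[str, object],
    config: Optional[ExtractionConfig] = None,
    recording_id: Optional[str] = None,
) -> pd.Series:
    """Per-recording prosodic feature vector.

    ``waveforms`` maps task labels to waveforms; ``counting`` may be a list of
    trials, which are concatenated before analysis.  Only ``free_speech`` and
    ``counting`` enter the feature set; a missing task yields NaN for all its
    features (missing values, not zeros).
    """
    cfg = config or ExtractionConfig()
    if not any(t in waveforms for t in TASKS):
        raise ValueError("need at least one of free_speech / counting")
    grid = cfg.grid()
    values: Dict[str, float] = {}
    for task in TASKS:
        wf = waveforms.get(task)
        if wf is not None and task == "counting" and isinstance(wf, (list, tuple)):
            wf = np.concatenate([np.asarray(w, dtype=float) for w in wf])
        contours = _base_contours(np.asarray(wf, dtype=float), cfg) if wf is not None else None
        for signal in SIGNALS:
            for k, span in enumerate(grid, start=1):
                layers: Dict[str, Optional[Contour]] = {"contour": None, "derivative": None}
                if contours is not None:
                    sm = smooth(contours[signal], span)
                    step = max(1, grid.window_frames(span) // 2)
                    dec = decimate_contour(sm, step)
                    layers["contour"] = dec
                    layers["derivative"] = derivative(dec)
                for layer in LAYERS:
                    c = layers[layer]
                    stats = contour_stats(c) if c is not None else {s: np.nan for s in STAT_NAMES}
                    for stat in STAT_NAMES:
                        values[feature_name(signal, task, k, span, layer, stat)] = stats[stat]
    ser = pd.Series(values, dtype=float)
    ser.name = recording_id
    return ser


@dataclass
class FeatureMatrix:
    """Per-recording features plus row metadata (participant, group, confounds)."""

    features: pd.DataFrame          # rows = recordings, columns = features
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.features.shape[0] < 1:
            raise ValueError("feature matrix needs at least one row")
        if len(self.meta) and not self.meta.index.equals(self.features.index):
            raise ValueError("meta index must match feature index")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_csv(self, features_path, meta_path=None) -> None:
        self.features.to_csv(features_path, index_label="recording_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, index_label="recording_id")


@dataclass
class FilterReport:
    dropped_low_variance: list
    dropped_low_unique: list
    n_before: int
    n_after: int

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "dropped_low_variance": list(self.dropped_low_variance),
            "dropped_low_unique": list(self.dropped_low_unique),
        }


def filter_features(
    matrix: FeatureMatrix,
    var_eps: float = 2.2e-16,
    min_unique: int = 100,
) -> tuple[FeatureMatrix, FilterReport]:
    """Drop near-constant and low-cardinality feature columns.

    A column is removed if its variance over non-missing rows is below
    ``var_eps`` or it takes fewer than ``min_unique`` distinct non-missing
    values.  The variance rule takes priority in the report when both apply.
    """
    X = matrix.features
    variances = X.var(axis=0, ddof=1, skipna=True)
    n_unique = X.nunique(dropna=True)
    low_var = variances.index[(variances < var_eps) | variances.isna()].tolist()
    low_unique = [c for c in X.columns if n_unique[c] < min_unique and c not in set(low_var)]
    keep = [c for c in X.columns if c not in set(low_var) and c not in set(low_unique)]
    if not keep:
        raise ValueError("feature filter removed every column")
    report = FilterReport(low_var, low_unique, X.shape[1], len(keep))
    return FeatureMatrix(X[keep].copy(), matrix.meta.copy()), report
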