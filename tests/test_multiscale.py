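"""Multi-timescale features: span grid, smoothing, derivatives, statistics,
assembly, and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prosovoice.audio_features import Contour, LOUDNESS_EXPONENT
from prosovoice.multiscale import (
    FEATURES_PER_RECORDING,
    FeatureMatrix,
    contour_stats,
    default_span_grid,
    derivative,
    extract_features,
    feature_name,
    filter_features,
    parse_feature_name,
    smooth,
)

HOP = 0.004


def contour(values, mask=None, hop=HOP):
    return Contour(np.asarray(values, dtype=float), hop, valid_mask=mask)


class TestSpanGrid:
    def test_grid_shape_and_extremes(self):
        g = default_span_grid(HOP)
        spans = np.asarray(g.spans)
        assert len(g) == 24
        assert spans[0] == pytest.approx(0.020)
        assert spans[-1] == pytest.approx(4.032)
        assert np.all(np.diff(spans) > 0)

    def test_named_chain_members_present(self):
        spans = [round(s, 4) for s in default_span_grid(HOP).spans]
        assert 0.252 in spans
        assert 0.1008 in spans

    def test_chain_arithmetic(self):
        assert 31.5 * 2**7 == 4032.0

    def test_windows_are_odd(self):
        g = default_span_grid(HOP)
        for s in g:
            assert g.window_frames(s) % 2 == 1

    def test_incompatible_hop_rejected(self):
        with pytest.raises(ValueError, match="hop"):
            default_span_grid(0.003)


class TestSmooth:
    def test_constant_is_fixed_point(self):
        c = contour([2.5] * 40)
        for span in (0.02, 0.1, 0.5):
            assert np.allclose(smooth(c, span).values, 2.5)

    def test_width_one_window_is_identity(self, rng):
        c = contour(rng.standard_normal(30))
        out = smooth(c, HOP)  # rounds to a 1-frame window
        assert np.allclose(out.values, c.values)

    def test_hand_computed_three_frame_average(self):
        c = contour([0, 0, 3, 0, 0])
        out = smooth(c, 3 * HOP)
        assert np.allclose(out.values, [0, 1, 1, 1, 0])

    def test_window_longer_than_segment_gives_segment_mean(self):
        c = contour([1, 2, 3])
        out = smooth(c, 99 * HOP)
        assert np.allclose(out.values, 2.0)

    def test_nan_splits_segments(self):
        vals = [1, 1, 1, np.nan, 5, 5, 5]
        out = smooth(contour(vals), 3 * HOP)
        assert np.allclose(out.values[:3], 1)
        assert np.isnan(out.values[3])
        assert np.allclose(out.values[4:], 5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(1, 23))
    def test_range_containment_and_variance_reduction(self, seed, span_idx):
        """Averaging stays inside [min, max] and larger spans never raise SD."""
        r = np.random.default_rng(seed)
        c = contour(r.standard_normal(80))
        g = default_span_grid(HOP)
        small = smooth(c, g.spans[span_idx - 1])
        large = smooth(c, g.spans[span_idx])
        assert small.values.min() >= c.values.min() - 1e-12
        assert small.values.max() <= c.values.max() + 1e-12
        assert np.std(large.values) <= np.std(small.values) + 1e-12


class TestDerivative:
    def test_constant_gives_zero(self):
        assert np.allclose(derivative(contour([4] * 10)).values, 0)

    def test_linear_ramp_slope(self):
        t = np.arange(20) * HOP
        d = derivative(contour(2.0 * t))
        assert np.allclose(d.values, 2.0)

    def test_sine_derivative_matches_cosine(self):
        # 1 Hz sine sampled at 250 Hz: >10x oversampled
        t = np.arange(250) * HOP
        d = derivative(contour(np.sin(2 * np.pi * t)))
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        err = np.abs(d.values[1:-1] - expected[1:-1]).max() / (2 * np.pi)
        assert err < 0.05

    def test_single_frame_gives_nan(self):
        assert np.isnan(derivative(contour([1.0])).values).all()


class TestContourStats:
    def test_flat_contour(self):
        s = contour_stats(contour([1, 1, 1, 1]))
        assert s["mean"] == 1 and s["sd"] == 0 and s["peak_count"] == 0
        assert s["min"] == 1 and s["max"] == 1

    def test_interior_strict_extrema(self):
        s = contour_stats(contour([0, 1, 0, 2, 0]))
        assert s["peak_count"] == 2
        assert s["valley_count"] == 1
        assert s["max"] == 2 and s["min"] == 0
        assert s["peak_prominence"] == pytest.approx(1.5)  # prominences 1 and 2

    def test_median_linear_interpolation(self):
        s = contour_stats(contour([0, 1, 2, 3]))
        assert s["q50"] == pytest.approx(1.5)

    def test_single_frame_partial_stats(self):
        s = contour_stats(contour([2.0]))
        assert s["mean"] == 2.0 and np.isnan(s["sd"]) and np.isnan(s["curvature"])

    def test_mask_excludes_frames(self):
        s = contour_stats(contour([0, 100, 0, 0], mask=np.array([1, 0, 1, 1], bool)))
        assert s["max"] == 0

    def test_oracle_equivalence_brute_force(self, rng):
        """smooth + derivative + stats match direct-definition recomputation."""
        for _ in range(25):
            vals = rng.standard_normal(50)
            c = contour(vals)
            span = float(rng.choice([3, 5, 9])) * HOP
            w = int(round(span / HOP))
            half = w // 2
            # brute-force moving average with shrinking edges
            sm = np.array([vals[max(i - half, 0): i + half + 1].mean()
                           for i in range(50)])
            out = smooth(c, span)
            assert np.allclose(out.values, sm, atol=1e-10)
            # brute-force derivative
            d = np.empty(50)
            d[0] = (sm[1] - sm[0]) / HOP
            d[-1] = (sm[-1] - sm[-2]) / HOP
            for i in range(1, 49):
                d[i] = (sm[i + 1] - sm[i - 1]) / (2 * HOP)
            assert np.allclose(derivative(out).values, d, atol=1e-10)
            # brute-force statistics on the smoothed contour
            s = contour_stats(out)
            assert s["mean"] == pytest.approx(sm.mean(), abs=1e-10)
            assert s["sd"] == pytest.approx(sm.std(ddof=1), abs=1e-10)
            assert s["q75"] == pytest.approx(np.quantile(sm, 0.75), abs=1e-10)
            peaks = sum(1 for i in range(1, 49) if sm[i - 1] < sm[i] > sm[i + 1])
            valleys = sum(1 for i in range(1, 49) if sm[i - 1] > sm[i] < sm[i + 1])
            assert s["peak_count"] == peaks and s["valley_count"] == valleys
            curv = np.abs(sm[2:] - 2 * sm[1:-1] + sm[:-2]) / HOP**2
            assert s["curvature"] == pytest.approx(curv.mean(), rel=1e-10)


class TestExtractFeatures:
    def test_feature_count_and_schema(self, small_waveforms):
        vec = extract_features(small_waveforms)
        assert len(vec) == FEATURES_PER_RECORDING
        info = parse_feature_name(vec.index[0])
        assert info["signal"] in ("loudness", "f0")
        rt = feature_name(info["signal"], info["task"], info["span_idx"],
                          info["span_s"], info["layer"], info["stat"])
        assert rt == vec.index[0]

    def test_deterministic_on_identical_waveforms(self, small_waveforms):
        a = extract_features(small_waveforms)
        b = extract_features(small_waveforms)
        pd.testing.assert_series_equal(a, b)

    def test_missing_task_gives_missing_values(self, small_waveforms):
        vec = extract_features({"free_speech": small_waveforms["free_speech"]})
        counting = [n for n in vec.index if parse_feature_name(n)["task"] == "counting"]
        assert vec[counting].isna().all()
        free = [n for n in vec.index if parse_feature_name(n)["task"] == "free_speech"]
        assert vec[free].notna().mean() > 0.9

    def test_no_task_rejected(self):
        with pytest.raises(ValueError, match="free_speech"):
            extract_features({"vowels": np.zeros(1000)})

    def test_doubled_amplitude_scales_loudness_not_f0(self, small_waveforms):
        base = extract_features(small_waveforms)
        doubled = {"free_speech": 2 * small_waveforms["free_speech"],
                   "counting": [2 * w for w in small_waveforms["counting"]]}
        vec = extract_features(doubled)
        scale = 4.0**LOUDNESS_EXPONENT
        loc = [n for n in base.index
               if (lambda i: i["signal"] == "loudness" and i["layer"] == "contour"
                   and i["stat"] in ("mean", "min", "max", "q25", "q50", "q75"))(
                       parse_feature_name(n))]
        ratio = vec[loc] / base[loc]
        ok = ratio[np.isfinite(ratio) & (base[loc].abs() > 1e-9)]
        assert np.allclose(ok, scale, rtol=0.02)
        f0_names = [n for n in base.index
                    if parse_feature_name(n)["signal"] == "f0"]
        d = (vec[f0_names] - base[f0_names]).abs()
        assert np.nanquantile(d.to_numpy(), 0.95) < 1e-3


class TestFilterFeatures:
    def _matrix(self, data):
        return FeatureMatrix(pd.DataFrame(data))

    def test_constant_column_dropped_by_variance_rule(self, rng):
        fm = self._matrix({"a": rng.standard_normal(150), "b": np.ones(150)})
        out, report = filter_features(fm, min_unique=10)
        assert list(out.features.columns) == ["a"]
        assert report.dropped_low_variance == ["b"]

    def test_low_unique_column_dropped(self, rng):
        fm = self._matrix({"a": rng.standard_normal(150),
                           "b": np.tile([0.0, 1.0, 2.0], 50)})
        out, report = filter_features(fm, min_unique=100)
        assert list(out.features.columns) == ["a"]
        assert report.dropped_low_unique == ["b"]

    def test_min_unique_one_disables_unique_rule(self, rng):
        fm = self._matrix({"a": rng.standard_normal(150),
                           "b": np.tile([0.0, 1.0], 75)})
        out, _ = filter_features(fm, min_unique=1)
        assert out.n_features == 2

    def test_all_columns_dropped_is_an_error(self):
        fm = self._matrix({"a": np.ones(10)})
        with pytest.raises(ValueError, match="every column"):
            filter_features(fm, min_unique=1)

    def test_study_scale_fixture_6145_to_6141(self, rng):
        """6145 columns, exactly 4 with < 100 unique values -> 6141 survive."""
        n = 150
        X = pd.DataFrame(rng.standard_normal((n, 6141)),
                         columns=[f"c{j}" for j in range(6141)])
        for j in range(4):
            X[f"lowu{j}"] = np.tile(np.arange(j + 2, dtype=float), n)[:n]
        fm = FeatureMatrix(X)
        assert fm.n_features == 6145
        out, report = filter_features(fm)
        assert out.n_features == 6141
        assert len(report.dropped_low_unique) == 4
        assert len(report.dropped_low_variance) == 0
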