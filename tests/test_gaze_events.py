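"""Gaze cleaning: segment splitting, velocity-threshold saccade detection
(checked against a brute-force oracle), binocular merging, and
displacement-zeroed gaze reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilswitch.gaze_events import (
    binocular_merge,
    clean_gaze,
    detect_saccades,
    median_sd,
    merge_intervals,
    moving_difference_velocity,
    split_contiguous,
)
from pupilswitch.types import GazeRecording, OcularEvent


def brute_force_saccades(x, y, fs, min_dur_ms=6.0, lambda_sd=6.0):
    """Independent oracle: direct velocity computation + thresholding,
    run-finding by linear scan."""
    def vel(p):
        v = np.zeros(len(p))
        for i in range(2, len(p) - 2):
            v[i] = (p[i + 2] + p[i + 1] - p[i - 1] - p[i - 2]) / (6.0 / fs)
        v[0] = v[1] = v[2]
        v[-1] = v[-2] = v[-3]
        return v

    vx, vy = vel(np.asarray(x, float)), vel(np.asarray(y, float))
    ex = lambda_sd * np.sqrt(np.median(vx ** 2) - np.median(vx) ** 2)
    ey = lambda_sd * np.sqrt(np.median(vy ** 2) - np.median(vy) ** 2)
    if ex == 0 and ey == 0:
        return []
    crit = [
        ((vx[i] / ex) ** 2 if ex > 0 else (np.inf if vx[i] != 0 else 0))
        + ((vy[i] / ey) ** 2 if ey > 0 else (np.inf if vy[i] != 0 else 0)) > 1
        for i in range(len(vx))
    ]
    min_n = max(int(round(min_dur_ms * fs / 1000.0)), 1)
    runs, start = [], None
    for i, c in enumerate(crit + [False]):
        if c and start is None:
            start = i
        elif not c and start is not None:
            if i - start >= min_n:
                runs.append((start, i))
            start = None
    return runs


class TestSplitContiguous:
    def test_threshold_boundary(self):
        valid = np.concatenate([
            np.ones(3), np.zeros(1), np.ones(5), np.zeros(1), np.ones(100)])
        segs = split_contiguous(valid.astype(bool))
        assert [b - a for a, b in segs] == [5, 100]

    def test_gap_free_recording_is_one_segment(self):
        segs = split_contiguous(np.ones(60000, dtype=bool))
        assert segs == [(0, 60000)]

    def test_alternating_samples_yield_nothing(self):
        valid = np.tile([True, False], 50)
        assert split_contiguous(valid) == []

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            split_contiguous(np.empty(0, dtype=bool))


class TestDetectSaccades:
    def test_pure_drift_produces_almost_no_saccades(self):
        # at 6 median-based SDs, plain Gaussian drift essentially never
        # crosses threshold for >= 6 consecutive samples
        rng = np.random.default_rng(0)
        total = 0
        for _ in range(100):
            n = 1000
            t = np.arange(n, dtype=float)
            x = 0.004 * t + rng.normal(0, 0.02, n)
            y = rng.normal(0, 0.02, n)
            total += len(detect_saccades(t, x, y, 1000.0))
        assert total <= 2

    def test_injected_excursion_detected_exactly_once(self):
        rng = np.random.default_rng(1)
        t = np.arange(2000, dtype=float)
        x = rng.normal(0, 0.02, 2000)
        y = rng.normal(0, 0.02, 2000)
        x[1000:1010] += np.cumsum(np.full(10, 1.0))  # ~50x background velocity
        events = detect_saccades(t, x, y, 1000.0)
        assert len(events) == 1
        assert events[0].onset_ms <= 1000 and events[0].offset_ms >= 1008

    def test_subminimum_excursion_ignored(self):
        rng = np.random.default_rng(2)
        t = np.arange(2000, dtype=float)
        x = rng.normal(0, 0.02, 2000)
        y = rng.normal(0, 0.02, 2000)
        x[1000:1003] += np.cumsum(np.full(3, 1.0))
        x[1003:] += 3.0
        # the injected run is 3 samples; with the velocity filter's spread it
        # stays under the 6-sample minimum
        events = detect_saccades(t, x, y, 1000.0, min_dur_ms=8.0)
        assert len(events) == 0

    def test_constant_segment_yields_no_events_and_no_error(self):
        t = np.arange(100, dtype=float)
        assert detect_saccades(t, np.ones(100), np.ones(100), 1000.0) == []

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(60):
            n = rng.integers(50, 300)
            x = np.cumsum(rng.normal(0, 0.05, n))
            y = np.cumsum(rng.normal(0, 0.05, n))
            if trial % 2:
                i = int(rng.integers(10, n - 20))
                x[i:i + 8] += np.cumsum(np.full(8, 2.0))
                x[i + 8:] += x[i + 7] - x[i + 8]
            t = np.arange(n, dtype=float)
            got = [(int(e.onset_ms), int(e.offset_ms)) for e in
                   detect_saccades(t, x, y, 1000.0)]
            expected = brute_force_saccades(x, y, 1000.0)
            assert got == [(a, b) for a, b in expected]

    def test_velocity_filter_matches_definition(self):
        p = np.arange(10, dtype=float) ** 2
        v = moving_difference_velocity(p, 1000.0)
        i = 5
        assert v[i] == pytest.approx((p[i + 2] + p[i + 1] - p[i - 1] - p[i - 2]) / 0.006)

    def test_median_sd_robust_to_outliers(self):
        v = np.concatenate([np.random.default_rng(0).normal(0, 1, 1000), [1e6]])
        assert median_sd(v) < 2.0


def ev(kind, a, b):
    return OcularEvent(kind, float(a), float(b))


class TestBinocularMerge:
    def test_overlapping_events_span_union(self):
        out = binocular_merge([ev("saccade", 100, 150)], [ev("saccade", 140, 180)])
        assert len(out) == 1
        assert (out[0].onset_ms, out[0].offset_ms) == (100, 180)
        assert out[0].binocular

    def test_disjoint_events_kept_monocular(self):
        out = binocular_merge([ev("saccade", 0, 10)], [ev("saccade", 20, 30)])
        assert len(out) == 2
        assert not any(e.binocular for e in out)

    def test_chain_overlap_closure(self):
        # A overlaps B, B overlaps C -> one event A.onset..C.offset,
        # oracle = interval union
        left = [ev("blink", 0, 50), ev("blink", 90, 140)]
        right = [ev("blink", 40, 100)]
        out = binocular_merge(left, right)
        ivs = [(e.onset_ms, e.offset_ms) for e in left + right]
        assert [(e.onset_ms, e.offset_ms) for e in out] == merge_intervals(ivs)
        assert len(out) == 1

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)),
                    max_size=8),
           st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)),
                    max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_merge_idempotent_and_order_invariant(self, lefts, rights):
        def mk(pairs):
            evs = [ev("saccade", a, a + d) for a, d in pairs]
            # per-eye lists are non-overlapping by construction upstream
            return binocular_merge(evs, [])

        l, r = mk(lefts), mk(rights)
        once = binocular_merge(l, r)
        twice = binocular_merge(once, [])
        spans = lambda es: [(e.onset_ms, e.offset_ms) for e in es]
        assert spans(twice) == spans(once)
        assert spans(binocular_merge(r, l)) == spans(once)


def _recording(x, y=None, fs=1000.0):
    n = len(x)
    y = np.zeros(n) if y is None else y
    z = np.zeros(n)
    return GazeRecording(np.arange(n) * 1000.0 / fs, x.copy(), y.copy(), z,
                         x.copy(), y.copy(), z.copy(),
                         [(0.0, n * 1000.0 / fs)], fs)


class TestCleanGaze:
    def test_saccade_step_removed_from_linear_drift(self):
        x = 0.01 * np.arange(1000, dtype=float)
        x[500:] += 5.0  # instantaneous jump at the saccade
        rec = _recording(x)
        out = clean_gaze(rec, [ev("saccade", 495, 505)], [], sacc_pad_ms=5)
        resid = out["x"] - 0.01 * np.arange(1000)
        # the 5-unit step is gone; only the drift inside the zeroed window
        # (~0.2 units over 21 samples) remains unaccounted
        assert np.ptp(resid) < 0.3

    def test_no_events_returns_binocular_mean(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(0, 0.1, 500))
        rec = _recording(x)
        out = clean_gaze(rec, [], [])
        np.testing.assert_allclose(out["x"], x, atol=1e-12)

    def test_displacement_zero_inside_padded_windows(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(0, 0.5, 2000))
        rec = _recording(x)
        sacc = [ev("saccade", 300, 330), ev("saccade", 350, 380)]
        out = clean_gaze(rec, sacc, [], sacc_pad_ms=20)
        m = out["zero_mask"]
        dx = np.diff(out["x"])
        inside = m[1:] & m[:-1]
        assert np.all(dx[inside] == 0)
        # abutting padded windows act as one zero-displacement span
        assert np.all(m[280:400])

    def test_one_eye_missing_uses_other(self):
        x = np.arange(100, dtype=float)
        rec = _recording(x)
        rec.xl[40:50] = np.nan
        rec.yl[40:50] = np.nan
        out = clean_gaze(rec, [], [])
        # right eye alone carries the signal through the gap
        np.testing.assert_allclose(np.diff(out["x"]), 1.0, atol=1e-12)
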