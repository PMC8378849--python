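"""Gaze-stream cleaning: contiguous segments, velocity-threshold saccade
detection, binocular event merging, and a saccade/blink-free gaze signal.

Saccades are detected per eye with the velocity-threshold algorithm of
Engbert & Kliegl: gaze velocity from a 5-sample moving-difference filter, an
elliptic threshold at ``lambda_sd`` median-based standard deviations per
component, and a minimum duration of 6 ms. Blinks are taken to be runs of
missing samples per eye (how video trackers emit signal loss). Overlapping
events from the two eyes are merged into binocular events spanning the
earlier onset and the later offset.
"""

from __future__ import annotations

import numpy as np

from .types import GazeRecording, OcularEvent


# ---------------------------------------------------------------------------
# segments and blinks
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    if len(mask) == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def split_contiguous(
    valid: np.ndarray, min_len: int = 5
) -> list[tuple[int, int]]:
    """Maximal runs of valid samples of length >= ``min_len`` (index ranges).

    Runs shorter than the minimum are discarded entirely, removing both
    signal-loss periods and fragments too short for saccade detection.
    """
    if len(valid) == 0:
        raise ValueError("empty recording")
    return [(a, b) for a, b in _runs(np.asarray(valid, bool)) if b - a >= min_len]


def detect_blinks_one_eye(
    time_ms: np.ndarray, lost: np.ndarray
) -> list[OcularEvent]:
    """Blink events as runs of missing samples for one eye."""
    dt = float(time_ms[1] - time_ms[0]) if len(time_ms) > 1 else 1.0
    return [
        OcularEvent("blink", float(time_ms[a]), float(time_ms[b - 1]) + dt)
        for a, b in _runs(np.asarray(lost, bool))
    ]


# ---------------------------------------------------------------------------
# saccade detection
# ---------------------------------------------------------------------------

def moving_difference_velocity(pos: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """5-sample moving-difference velocity estimate (units/s).

    v[i] = (p[i+2] + p[i+1] - p[i-1] - p[i-2]) / (6 dt); the two samples at
    each edge reuse the nearest interior estimate.
    """
    p = np.asarray(pos, dtype=float)
    n = len(p)
    if n < 5:
        raise ValueError("segment too short for the velocity filter")
    v = np.empty(n)
    dt = 1.0 / sample_rate_hz
    v[2:-2] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt)
    v[:2] = v[2]
    v[-2:] = v[-3]
    return v


def median_sd(v: np.ndarray) -> float:
    """Median-based standard deviation: sqrt(median(v^2) - median(v)^2)."""
    return float(np.sqrt(np.median(v ** 2) - np.median(v) ** 2))


def detect_saccades(
    time_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    sample_rate_hz: float,
    min_dur_ms: float = 6.0,
    lambda_sd: float = 6.0,
) -> list[OcularEvent]:
    """Velocity-threshold saccade detection on one gap-free segment.

    A sample exceeds threshold when (vx/ex)^2 + (vy/ey)^2 > 1 with
    ek = lambda_sd * median-based SD of the velocity component; saccades are
    maximal supra-threshold runs lasting at least ``min_dur_ms``.
    """
    vx = moving_difference_velocity(x, sample_rate_hz)
    vy = moving_difference_velocity(y, sample_rate_hz)
    ex = lambda_sd * median_sd(vx)
    ey = lambda_sd * median_sd(vy)
    if ex == 0.0 and ey == 0.0:
        return []
    ellip = np.zeros(len(vx))
    for v, e in ((vx, ex), (vy, ey)):
        if e > 0:
            ellip += (v / e) ** 2
        else:  # degenerate axis: any motion on it exceeds threshold
            ellip += np.where(v != 0, np.inf, 0.0)
    crit = ellip > 1.0
    min_samples = max(int(round(min_dur_ms * sample_rate_hz / 1000.0)), 1)
    dt = 1000.0 / sample_rate_hz
    out = []
    for a, b in _runs(crit):
        if b - a >= min_samples:
            out.append(OcularEvent(
                "saccade", float(time_ms[a]), float(time_ms[b - 1]) + dt))
    return out


def detect_saccades_recording(
    rec: GazeRecording,
    min_dur_ms: float = 6.0,
    lambda_sd: float = 6.0,
    min_segment: int = 5,
) -> tuple[list[OcularEvent], list[OcularEvent]]:
    """Per-eye saccade lists over all contiguous segments of a recording."""
    out: list[list[OcularEvent]] = []
    for x, y in ((rec.xl, rec.yl), (rec.xr, rec.yr)):
        valid = ~(np.isnan(x) | np.isnan(y))
        events: list[OcularEvent] = []
        for a, b in split_contiguous(valid, min_segment):
            events.extend(detect_saccades(
                rec.time_ms[a:b], x[a:b], y[a:b], rec.sample_rate_hz,
                min_dur_ms, lambda_sd))
        out.append(events)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# binocular merging
# ---------------------------------------------------------------------------

def binocular_merge(
    events_left: list[OcularEvent], events_right: list[OcularEvent]
) -> list[OcularEvent]:
    """Merge temporally overlapping events across eyes into binocular events.

    Overlap is transitive: a chain of pairwise-overlapping events collapses to
    one event spanning the earliest onset and latest offset. Events that
    overlap nothing from the other eye are kept monocular. Idempotent and
    order-invariant.
    """
    tagged = [(e, "L") for e in events_left] + [(e, "R") for e in events_right]
    tagged.sort(key=lambda t: (t[0].onset_ms, t[0].offset_ms))
    out: list[OcularEvent] = []
    eyes: set[str] = set()
    for e, eye in tagged:
        if out and e.onset_ms < out[-1].offset_ms:  # strict overlap
            prev = out[-1]
            eyes.add(eye)
            out[-1] = OcularEvent(
                prev.kind, prev.onset_ms, max(prev.offset_ms, e.offset_ms),
                binocular=len(eyes) > 1 or prev.binocular or e.binocular)
        else:
            out.append(OcularEvent(
                e.kind, e.onset_ms, e.offset_ms, binocular=e.binocular))
            eyes = {eye}
    return out


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of possibly-overlapping [on, off) intervals (abutting merged)."""
    out: list[list[float]] = []
    for on, off in sorted(intervals):
        if out and on <= out[-1][1]:
            out[-1][1] = max(out[-1][1], off)
        else:
            out.append([on, off])
    return [(a, b) for a, b in out]


# ---------------------------------------------------------------------------
# cleaned gaze signal
# ---------------------------------------------------------------------------

def clean_gaze(
    rec: GazeRecording,
    saccades: list[OcularEvent],
    blinks: list[OcularEvent],
    sacc_pad_ms: float = 20.0,
    blink_pad_ms: float = 50.0,
) -> dict:
    """Eye-averaged gaze with displacement zeroed around saccades and blinks.

    Samples closer than ``sacc_pad_ms`` to a saccade or ``blink_pad_ms`` to a
    blink (and any remaining missing samples) contribute zero displacement:
    positions after each padded window are shifted so the across-window step
    is removed, leaving a continuous signal. Returns cleaned x, y, the time
    axis, and the mask of zero-displacement samples.
    """
    import warnings

    t = rec.time_ms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN samples
        xm = np.nanmean(np.vstack([rec.xl, rec.xr]), axis=0)
        ym = np.nanmean(np.vstack([rec.yl, rec.yr]), axis=0)

    windows = [(e.onset_ms - sacc_pad_ms, e.offset_ms + sacc_pad_ms) for e in saccades]
    windows += [(e.onset_ms - blink_pad_ms, e.offset_ms + blink_pad_ms) for e in blinks]
    windows = merge_intervals(windows)

    zero_mask = np.isnan(xm) | np.isnan(ym)
    for on, off in windows:
        i0, i1 = np.searchsorted(t, on, "left"), np.searchsorted(t, off, "left")
        zero_mask[i0:i1] = True

    out = {}
    for name, sig in (("x", xm), ("y", ym)):
        d = np.diff(np.nan_to_num(sig, nan=0.0))
        # a step is removed when either endpoint sits in a padded window
        kill = zero_mask[1:] | zero_mask[:-1]
        d[kill] = 0.0
        start = sig[~np.isnan(sig)][0] if np.any(~np.isnan(sig)) else 0.0
        out[name] = np.concatenate(([start], start + np.cumsum(d)))
    return {"time_ms": t, "x": out["x"], "y": out["y"], "zero_mask": zero_mask}
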