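"""Perceptual-state decoding from the cleaned optokinetic-nystagmus gaze signal.

A 750 ms window slides over the cleaned gaze position in 38 ms steps; per
window, least-squares slopes of horizontal and vertical position give a gaze
displacement angle whose cosine is +1 for due-rightward and -1 for
due-leftward drift. Values above +0.85 are assigned to one percept, below
-0.85 to the other; switch moments lie midway between adjacent
opposite-percept periods, with switches suppressed whenever they would
create a dominance episode briefer than 500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .types import Episode, OcularEvent, PerceptTimeline, Switch, OTHER_STATE

STATE_OF_SIGN = {1: "A", -1: "B"}


@dataclass
class DirectionSeries:
    """Windowed gaze-displacement direction (cosine of the drift angle)."""

    times_ms: np.ndarray   # window centers
    values: np.ndarray     # in [-1, 1]; NaN where unpatchable
    window_ms: float = 750.0
    step_ms: float = 38.0


# ---------------------------------------------------------------------------
# windowed displacement direction
# ---------------------------------------------------------------------------

def _sliding_slopes(sig: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    """Least-squares slope of ``sig`` vs sample index over [s, s+w) windows."""
    c = np.concatenate(([0.0], np.cumsum(sig)))
    ci = np.concatenate(([0.0], np.cumsum(sig * np.arange(len(sig), dtype=float))))
    s = np.asarray(starts)
    sum_p = c[s + w] - c[s]
    sum_ip = (ci[s + w] - ci[s]) - s * sum_p
    num = sum_ip - (w - 1) / 2.0 * sum_p
    den = w * (w * w - 1) / 12.0
    return num / den


def windowed_direction(
    time_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    trials: list[tuple[float, float]],
    window_ms: float = 750.0,
    step_ms: float = 38.0,
) -> DirectionSeries:
    """Cosine of the gaze-displacement angle per sliding window.

    Windows never span a trial boundary; each value is assigned to the window
    center. The cosine equals sx / sqrt(sx^2 + sy^2) for slopes (sx, sy); a
    window with zero displacement in both components yields 0 (unclassifiable).
    """
    dt = float(time_ms[1] - time_ms[0])
    w = max(int(round(window_ms / dt)), 2)
    step = max(int(round(step_ms / dt)), 1)
    centers, values = [], []
    for t0, t1 in trials:
        i0 = int(np.searchsorted(time_ms, t0, "left"))
        i1 = int(np.searchsorted(time_ms, t1, "left"))
        if i1 - i0 < w:
            continue
        starts = np.arange(i0, i1 - w + 1, step)
        sx = _sliding_slopes(x, starts, w)
        sy = _sliding_slopes(y, starts, w)
        norm = np.hypot(sx, sy)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosv = np.where(norm > 0, sx / np.where(norm > 0, norm, 1.0), 0.0)
        centers.append(time_ms[starts] + (w - 1) / 2.0 * dt)
        values.append(cosv)
    if centers:
        t = np.concatenate(centers)
        v = np.concatenate(values)
    else:
        t, v = np.empty(0), np.empty(0)
    return DirectionSeries(t, v, window_ms, step_ms)


# ---------------------------------------------------------------------------
# blink patching
# ---------------------------------------------------------------------------

def patch_blink_windows(
    series: DirectionSeries,
    blinks: list[OcularEvent],
    pre_ms: float = 250.0,
    post_ms: float = 400.0,
    flank_ms: float = 100.0,
) -> DirectionSeries:
    """Replace direction values near blinks by the mean of the flanking values.

    Values whose window center falls in [onset - pre, offset + post] take the
    average of the series over the ``flank_ms`` stretches immediately before
    and after that interval (one-sided if the other flank is empty; NaN if
    both are, e.g. a blink at a trial edge). Flank means are computed on the
    unpatched values.
    """
    t, v = series.times_ms, series.values.copy()
    orig = series.values
    for b in sorted(blinks, key=lambda e: e.onset_ms):
        lo, hi = b.onset_ms - pre_ms, b.offset_ms + post_ms
        inside = (t >= lo) & (t <= hi)
        if not np.any(inside):
            continue
        left = (t >= lo - flank_ms) & (t < lo)
        right = (t > hi) & (t <= hi + flank_ms)
        means = []
        for flank in (left, right):
            vals = orig[flank]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                means.append(vals.mean())
        v[inside] = np.mean(means) if means else np.nan
    return DirectionSeries(t, v, series.window_ms, series.step_ms)


# ---------------------------------------------------------------------------
# percept assignment and switch marking
# ---------------------------------------------------------------------------

def assign_percepts(series: DirectionSeries, threshold: float = 0.85) -> np.ndarray:
    """Three-valued labels per window: +1 (A), -1 (B), 0 unassigned.

    Strict inequalities: a value exactly at the threshold stays unassigned.
    """
    v = series.values
    labels = np.zeros(len(v), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        labels[v > threshold] = 1
        labels[v < -threshold] = -1
    return labels


def _assigned_episodes(
    times: np.ndarray, labels: np.ndarray
) -> list[tuple[int, float, float]]:
    """Maximal same-state stretches of assigned points, bridging unassigned
    gaps between same-state neighbours (no switch across such gaps)."""
    idx = np.flatnonzero(labels != 0)
    eps: list[list[float]] = []  # [sign, start, end]
    for i in idx:
        s = int(labels[i])
        if eps and eps[-1][0] == s:
            eps[-1][2] = times[i]
        else:
            eps.append([s, times[i], times[i]])
    return [(int(a), float(b), float(c)) for a, b, c in eps]


def mark_switches(
    series_times_ms: np.ndarray,
    labels: np.ndarray,
    min_dominance_ms: float = 500.0,
    trial_bounds: tuple[float, float] | None = None,
) -> PerceptTimeline:
    """Switch moments midway between adjacent opposite-percept periods.

    Suppression of too-brief episodes proceeds deterministically left to
    right: the first inter-switch interval shorter than ``min_dominance_ms``
    has both bounding switches removed (re-merging the flanking same-state
    periods), and the scan repeats until stable. Episodes bounded on one side
    by the trial edge are not subject to the rule.
    """
    eps = _assigned_episodes(series_times_ms, labels)
    switch_t = [
        (prev_end + nxt_start) / 2.0
        for (_, _, prev_end), (_, nxt_start, _) in zip(eps[:-1], eps[1:])
    ]
    switch_d = [STATE_OF_SIGN[e[0]] for e in eps[1:]]

    changed = True
    while changed and len(switch_t) >= 2:
        changed = False
        for k in range(len(switch_t) - 1):
            if switch_t[k + 1] - switch_t[k] < min_dominance_ms:
                del switch_t[k:k + 2]
                del switch_d[k:k + 2]
                changed = True
                break

    switches = [Switch(t, d) for t, d in zip(switch_t, switch_d)]
    episodes: list[Episode] = []
    if eps:
        t_first, t_last = eps[0][1], eps[-1][2]
        if trial_bounds is not None:
            t_first, t_last = trial_bounds
        if switches:
            state = OTHER_STATE[switches[0].direction]
            bounds = [t_first] + [s.time_ms for s in switches] + [t_last]
            for a, b in zip(bounds[:-1], bounds[1:]):
                episodes.append(Episode(state, a, b))
                state = OTHER_STATE[state]
        else:
            episodes.append(Episode(STATE_OF_SIGN[eps[0][0]], t_first, t_last))
    tl = PerceptTimeline(episodes, switches)
    tl.validate()
    return tl


# ---------------------------------------------------------------------------
# full decode
# ---------------------------------------------------------------------------

def decode_recording(
    clean: dict,
    trials: list[tuple[float, float]],
    blinks: list[OcularEvent],
    cfg: RunConfig | None = None,
) -> tuple[PerceptTimeline, DirectionSeries]:
    """Cleaned gaze -> percept timeline, trial by trial."""
    cfg = cfg or RunConfig()
    series = windowed_direction(
        clean["time_ms"], clean["x"], clean["y"], trials,
        cfg.okn_window_ms, cfg.okn_step_ms)
    series = patch_blink_windows(
        series, blinks, cfg.blink_patch_pre_ms, cfg.blink_patch_post_ms,
        cfg.blink_patch_flank_ms)
    labels = assign_percepts(series, cfg.okn_threshold)

    all_eps: list[Episode] = []
    all_sw: list[Switch] = []
    for t0, t1 in trials:
        in_trial = (series.times_ms >= t0) & (series.times_ms < t1)
        tl = mark_switches(
            series.times_ms[in_trial], labels[in_trial],
            cfg.min_dominance_ms, trial_bounds=(t0, t1))
        all_eps.extend(tl.episodes)
        all_sw.extend(tl.switches)
    return PerceptTimeline(all_eps, all_sw), series


# ---------------------------------------------------------------------------
# correspondence validation against a reference event stream
# ---------------------------------------------------------------------------

def validate_against_reference(
    test_events_ms: np.ndarray,
    test_directions: list[str],
    ref_events_ms: np.ndarray,
    ref_directions: list[str],
    n_bins: int,
    deconv_window_s: tuple[float, float],
    hr_window_s: tuple[float, float],
    bin_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Deconvolved event-correspondence curve plus hit/false-alarm areas.

    Builds a 10 Hz indicator of the test events and FIR-deconvolves it
    against the reference events over a 3 s window, per switch direction,
    then averages the two curves. HR is the area inside ``hr_window_s``; FA
    the area under the remainder of the deconvolution window.
    """
    from .glm import fir_deconvolve

    test_events_ms = np.asarray(test_events_ms, float)
    ref_events_ms = np.asarray(ref_events_ms, float)
    if len(test_events_ms) < 2 or len(ref_events_ms) < 2:
        raise ValueError("need at least 2 events of each type")

    curves = []
    for d in ("A", "B"):
        te = test_events_ms[[x == d for x in test_directions]]
        re_ = ref_events_ms[[x == d for x in ref_directions]]
        if len(te) == 0 or len(re_) == 0:
            continue
        indicator = np.zeros(n_bins)
        bins = np.clip(np.round(te / bin_ms).astype(int), 0, n_bins - 1)
        indicator[bins] = 1.0
        curve = fir_deconvolve(indicator, re_, deconv_window_s, bin_ms=bin_ms)
        curves.append(curve.values)
        lags = curve.lags_s
    mean_curve = np.mean(curves, axis=0)
    in_hr = (lags >= hr_window_s[0]) & (lags <= hr_window_s[1])
    hr = float(mean_curve[in_hr].sum())
    fa = float(mean_curve[~in_hr].sum())
    return lags, mean_curve, hr, fa
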