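"""Harmonizing keypress streams and replay scripts with OKN timelines.

Manual reports use three keys: the two exclusive percepts and "mixture".
Converting a press stream to a timeline comparable with the (instantaneous,
mixture-free) OKN convention: repeated presses are dropped; an exclusive ->
mixture -> other-exclusive sequence collapses to a single switch at the
midpoint of the mixture period; exclusive -> mixture -> same-exclusive
("return transition") yields no switch; a direct exclusive -> exclusive
change switches at the second press time.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .synthetic import timeline_from_switches
from .types import PerceptTimeline

EXCLUSIVE = ("A", "B")
MIXTURE = "mixture"


def drop_repeats(presses: list[tuple[float, str]]) -> list[tuple[float, str]]:
    out: list[tuple[float, str]] = []
    for t, k in presses:
        if out and out[-1][1] == k:
            continue
        out.append((t, k))
    return out


def keypress_timeline(
    presses: list[tuple[float, str]],
    trial_bounds: list[tuple[float, float]],
) -> PerceptTimeline:
    """Percept timeline from a keypress stream (times in ms).

    The first exclusive press of a trial defines the state from the trial
    start; a mixture period at the trial end with no following exclusive
    press is discarded; consecutive mixture presses collapse to one period.
    """
    switch_t: list[float] = []
    switch_d: list[str] = []
    for t0, t1 in trial_bounds:
        trial = drop_repeats(
            [(t, k) for t, k in sorted(presses) if t0 <= t < t1])
        last_exclusive: str | None = None
        mixture_start: float | None = None
        for t, k in trial:
            if k == MIXTURE:
                if mixture_start is None:
                    mixture_start = t
                continue
            if last_exclusive is None:
                pass  # initial percept; no switch
            elif k == last_exclusive:
                pass  # return transition (or repeat): no switch
            elif mixture_start is not None:
                switch_t.append((mixture_start + t) / 2.0)
                switch_d.append(k)
            else:
                switch_t.append(t)
                switch_d.append(k)
            last_exclusive = k
            mixture_start = None
    return timeline_from_switches(np.array(switch_t), switch_d, trial_bounds)


def replay_script(
    presses: list[tuple[float, str]],
    trial_bounds: list[tuple[float, float]],
    rt_s: float = 0.5,
) -> list[tuple[float, str]]:
    """On-screen replay schedule from a report stream: every reported event
    shifted earlier by the fixed reaction time.

    Mixture periods keep their reported durations, including return
    transitions. A shift past the trial start is clipped to it.
    """
    out = []
    for t, k in sorted(presses):
        t_new = t - rt_s * 1000.0
        for t0, t1 in trial_bounds:
            if t0 <= t < t1:
                t_new = max(t_new, t0)
                break
        out.append((t_new, k))
    return out


def switch_rate_correlation(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of per-observer switch counts between two
    switch-identification methods. Returns (r, p)."""
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched counts for at least 3 observers")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in switch counts")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
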