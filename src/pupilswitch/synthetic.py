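"""Ground-truth generator for gaze + pupil recordings.

Simulates the statistical structure the analysis chain assumes:

* a hidden two-state percept timeline with gamma-distributed dominance
  durations, tiling each trial;
* optokinetic nystagmus: horizontal gaze drifts at the slow-phase speed in
  the direction of the current percept and is reset to straight-ahead by
  20-40 ms quick phases, giving the characteristic sawtooth;
* blinks as binocular missing-sample (NaN) intervals;
* report keypresses lagging switches by truncated-normal reaction times,
  ignore-task keypresses lagging dot-size probes whose onsets are spaced
  Uniform(3, 8) s apart;
* a pupil trace composed of per-trial exponential drift, a switch-locked
  constriction kernel (optionally modulated by the z-scored log preceding
  dominance duration), a keypress-locked dilation kernel, and white noise.

Everything is driven by a single ``numpy.random.Generator`` so that a fixed
seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .types import Episode, GazeRecording, PerceptTimeline, Switch, OTHER_STATE, STATE_SIGN

CONDITIONS = (
    "rivalry_report",
    "rivalry_ignore",
    "onscreen_report",
    "onscreen_ignore",
)


@dataclass
class GroundTruth:
    timeline: PerceptTimeline
    keypress_times_ms: np.ndarray
    probe_times_ms: np.ndarray
    blink_intervals_ms: list[tuple[float, float]]
    kernel_constriction: tuple[np.ndarray, np.ndarray]
    kernel_dilation: tuple[np.ndarray, np.ndarray]
    covariate_beta: float
    switch_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    pupil_components: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.timeline.validate()


@dataclass
class SimulatedCondition:
    name: str
    stimulus: str  # "rivalry" | "onscreen"
    task: str      # "report" | "ignore"
    recording: GazeRecording
    truth: GroundTruth
    trial_starts_ms: np.ndarray


# ---------------------------------------------------------------------------
# percept dynamics
# ---------------------------------------------------------------------------

def simulate_percept_timeline(cfg: SimConfig, rng: np.random.Generator) -> PerceptTimeline:
    """Alternating dominance episodes with i.i.d. gamma durations per trial.

    Durations are drawn until a trial is tiled; the last episode is truncated
    at the trial end. Switches are the interior episode boundaries.
    """
    episodes: list[Episode] = []
    switches: list[Switch] = []
    for t0, t1 in cfg.trial_bounds_ms():
        state = "A" if rng.random() < 0.5 else "B"
        t = t0
        while t < t1:
            dur = rng.gamma(cfg.dominance_gamma_shape, cfg.dominance_gamma_scale) * 1000.0
            end = min(t + dur, t1)
            episodes.append(Episode(state, t, end))
            if end < t1:
                state = OTHER_STATE[state]
                switches.append(Switch(end, state))
            t = end
    tl = PerceptTimeline(episodes, switches)
    tl.validate()
    return tl


def timeline_from_switches(
    switch_times_ms: np.ndarray,
    directions: list[str],
    trial_bounds_ms: list[tuple[float, float]],
) -> PerceptTimeline:
    """Rebuild an episode timeline from switch moments (e.g. a replay schedule)."""
    episodes: list[Episode] = []
    switches = [Switch(float(t), d) for t, d in zip(switch_times_ms, directions)]
    for t0, t1 in trial_bounds_ms:
        in_trial = [s for s in switches if t0 < s.time_ms < t1]
        if not in_trial:
            episodes.append(Episode("A", t0, t1))
            continue
        first_state = OTHER_STATE[in_trial[0].direction]
        bounds = [t0] + [s.time_ms for s in in_trial] + [t1]
        state = first_state
        for a, b in zip(bounds[:-1], bounds[1:]):
            episodes.append(Episode(state, a, b))
            state = OTHER_STATE[state]
    tl = PerceptTimeline(episodes, switches)
    tl.validate()
    return tl


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def _direction_per_sample(timeline: PerceptTimeline, t_ms: np.ndarray) -> np.ndarray:
    """Signed slow-phase direction (+1 rightward / A, -1 leftward / B, 0 off-trial)."""
    sign = np.zeros(len(t_ms))
    for ep in timeline.episodes:
        lo = np.searchsorted(t_ms, ep.onset_ms, side="left")
        hi = np.searchsorted(t_ms, ep.offset_ms, side="left")
        sign[lo:hi] = STATE_SIGN[ep.state]
    return sign


def _draw_blinks(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for t0, t1 in cfg.trial_bounds_ms():
        n = rng.poisson(cfg.blink_rate_hz * cfg.trial_len_s)
        onsets = np.sort(rng.uniform(t0, t1, size=n))
        durs = rng.uniform(*cfg.blink_dur_ms_range, size=n)
        last_end = -np.inf
        for on, d in zip(onsets, durs):
            off = min(on + d, t1)
            if on - last_end < 300.0 or off <= on:  # keep blinks well separated
                continue
            out.append((float(on), float(off)))
            last_end = off
    return out


def simulate_gaze(
    timeline: PerceptTimeline, cfg: SimConfig, rng: np.random.Generator
) -> tuple[GazeRecording, list[tuple[float, float]]]:
    """Binocular sawtooth OKN gaze traces following the hidden percept.

    Returns the recording (pupil columns zero-filled; use :func:`simulate_pupil`
    to populate them) and the list of blink intervals inserted as NaN runs.
    """
    dt_ms = 1000.0 / cfg.sample_rate_hz
    n = int(round(cfg.trial_bounds_ms()[-1][1] / dt_ms))
    t_ms = np.arange(n) * dt_ms

    sign = _direction_per_sample(timeline, t_ms)
    slow = np.cumsum(sign * cfg.slow_phase_speed / cfg.sample_rate_hz)

    # quick phases: renewal process per trial, each a linear reset to zero
    resets: list[tuple[float, float]] = []
    for t0, t1 in cfg.trial_bounds_ms():
        t = t0 + 1000.0 * rng.gamma(4.0, cfg.quick_phase_interval_s / 4.0)
        while t < t1:
            d = rng.uniform(*cfg.quick_phase_dur_ms_range)
            resets.append((t, min(t + d, t1)))
            t += 1000.0 * rng.gamma(4.0, cfg.quick_phase_interval_s / 4.0)
    x = np.empty(n)
    offset = 0.0  # cumulative slow displacement already cancelled by resets
    seg_start = 0
    for on, off in resets:
        i0 = min(int(np.searchsorted(t_ms, on)), n - 2)
        i1 = min(max(int(np.searchsorted(t_ms, off)), i0 + 2), n)
        x[seg_start:i0] = slow[seg_start:i0] - offset
        # ramp the position from its pre-reset value back to zero
        x[i0:i1] = np.linspace(slow[i0] - offset, 0.0, i1 - i0)
        offset = slow[i1 - 1]
        seg_start = i1
    x[seg_start:] = slow[seg_start:] - offset

    noise = lambda: rng.normal(0.0, cfg.gaze_noise_sd, size=n)
    xl, xr = x + noise(), x + noise()
    yl, yr = noise(), noise()

    blinks = _draw_blinks(cfg, rng)
    for on, off in blinks:
        i0, i1 = int(np.searchsorted(t_ms, on)), int(np.searchsorted(t_ms, off))
        for arr in (xl, yl, xr, yr):
            arr[i0:i1] = np.nan

    rec = GazeRecording(
        time_ms=t_ms, xl=xl, yl=yl, pl=np.zeros(n), xr=xr, yr=yr,
        pr=np.zeros(n), trials=cfg.trial_bounds_ms(),
        sample_rate_hz=cfg.sample_rate_hz,
    )
    return rec, blinks


# ---------------------------------------------------------------------------
# keypresses and probes
# ---------------------------------------------------------------------------

def _truncnorm_rt_ms(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Reaction times > rt_min_s, normal(rt_mean, rt_sd) otherwise (rejection)."""
    out = rng.normal(cfg.rt_mean_s, cfg.rt_sd_s, size=size)
    bad = out <= cfg.rt_min_s
    while np.any(bad):
        out[bad] = rng.normal(cfg.rt_mean_s, cfg.rt_sd_s, size=int(bad.sum()))
        bad = out <= cfg.rt_min_s
    return out * 1000.0


def simulate_probes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Dot-size probe onsets: renewal gaps Uniform(probe_interval_range_s)."""
    lo, hi = cfg.probe_interval_range_s
    times = []
    for t0, t1 in cfg.trial_bounds_ms():
        t = t0 + 1000.0 * rng.uniform(lo, hi)
        while t < t1:
            times.append(t)
            t += 1000.0 * rng.uniform(lo, hi)
    return np.array(times)


def simulate_keypresses_and_probes(
    timeline: PerceptTimeline, cfg: SimConfig, rng: np.random.Generator,
    task: str = "report",
) -> tuple[np.ndarray, np.ndarray]:
    """Keypress times for a task mode; returns (keypresses_ms, probes_ms).

    Report mode: one press per switch, lagging it by a truncated-normal RT;
    presses that would fall after the trial end are dropped (never emitted).
    Ignore mode: presses follow detected probes (detection probability
    ``probe_detect_prob``); probes are returned so that unreported ones can be
    identified downstream.
    """
    bounds = cfg.trial_bounds_ms()

    def trial_end_of(t: float) -> float:
        for t0, t1 in bounds:
            if t0 <= t < t1:
                return t1
        return -np.inf

    if task == "report":
        sw = timeline.switch_times
        rts = _truncnorm_rt_ms(cfg, rng, len(sw))
        kp = sw + rts
        keep = np.array([k < trial_end_of(s) for k, s in zip(kp, sw)])
        return kp[keep], np.empty(0)
    if task == "ignore":
        probes = simulate_probes(cfg, rng)
        detected = rng.random(len(probes)) < cfg.probe_detect_prob
        rts = _truncnorm_rt_ms(cfg, rng, len(probes))
        kp = probes + rts
        keep = detected & np.array([k < trial_end_of(p) for k, p in zip(kp, probes)])
        return kp[keep], probes
    raise ValueError(f"unknown task mode {task!r}")


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

def preceding_durations_ms(timeline: PerceptTimeline) -> np.ndarray:
    """Duration of the dominance episode terminated by each switch."""
    ends = {ep.offset_ms: ep for ep in timeline.episodes}
    out = []
    for s in timeline.switches:
        ep = ends.get(s.time_ms)
        if ep is None:  # numeric lookup fallback
            ep = min(timeline.episodes, key=lambda e: abs(e.offset_ms - s.time_ms))
        out.append(ep.duration_ms)
    return np.array(out)


def zscore_log(values: np.ndarray) -> np.ndarray:
    """z-scored log transform with a zero-variance guard (all-equal -> zeros)."""
    v = np.log(np.asarray(values, dtype=float))
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def resample_kernel(
    lags_s: np.ndarray, values: np.ndarray, sample_rate_hz: float
) -> np.ndarray:
    """Kernel samples on the recording grid, from lag 0 to the kernel support."""
    dt_s = 1.0 / sample_rate_hz
    grid = np.arange(0.0, lags_s[-1] + dt_s / 2, dt_s)
    return np.interp(grid, lags_s, values)


def _stamp_kernel(
    trace: np.ndarray, event_ms: float, amp: float, kern: np.ndarray, dt_ms: float
) -> None:
    i0 = int(round(event_ms / dt_ms))
    i1 = min(i0 + len(kern), len(trace))
    if i0 >= len(trace) or i1 <= max(i0, 0):
        return
    k0 = max(0, -i0)
    trace[max(i0, 0):i1] += amp * kern[k0:k0 + (i1 - max(i0, 0))]


def simulate_pupil(
    timeline: PerceptTimeline,
    keypresses_ms: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pupil trace (kernel units) on the recording's uniform time axis.

    trace = per-trial drift + sum_i a_i * K_con(t - switch_i)
          + sum_k K_dil(t - press_k) + white noise,
    a_i = 1 + covariate_beta * z(log preceding dominance duration).

    Returns (t_ms, trace, components) where ``components`` holds each additive
    part plus the per-switch amplitudes.
    """
    dt_ms = 1000.0 / cfg.sample_rate_hz
    n = int(round(cfg.trial_bounds_ms()[-1][1] / dt_ms))
    t_ms = np.arange(n) * dt_ms

    drift = np.zeros(n)
    for t0, t1 in cfg.trial_bounds_ms():
        i0, i1 = int(round(t0 / dt_ms)), int(round(t1 / dt_ms))
        rel_s = (t_ms[i0:i1] - t0) / 1000.0
        drift[i0:i1] = cfg.drift_amp * np.exp(-rel_s / cfg.drift_tau_s)

    kc_l, kc_v = cfg.constriction_kernel()
    kd_l, kd_v = cfg.dilation_kernel()
    if len(timeline.switches):
        amps = 1.0 + cfg.covariate_beta * zscore_log(preceding_durations_ms(timeline))
    else:
        amps = np.empty(0)

    kc = resample_kernel(kc_l, kc_v, cfg.sample_rate_hz)
    kd = resample_kernel(kd_l, kd_v, cfg.sample_rate_hz)
    switch_part = np.zeros(n)
    for s, a in zip(timeline.switches, amps):
        _stamp_kernel(switch_part, s.time_ms, a, kc, dt_ms)
    press_part = np.zeros(n)
    for k in np.asarray(keypresses_ms, dtype=float):
        _stamp_kernel(press_part, k, 1.0, kd, dt_ms)

    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    trace = drift + switch_part + press_part + noise
    components = {
        "drift": drift, "switch": switch_part, "keypress": press_part,
        "noise": noise, "switch_amplitudes": amps,
    }
    return t_ms, trace, components


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def simulate_condition(
    cfg: SimConfig,
    rng: np.random.Generator,
    stimulus: str = "rivalry",
    task: str = "report",
    timeline: PerceptTimeline | None = None,
) -> SimulatedCondition:
    """One observer-condition: gaze + pupil recording with full ground truth."""
    if timeline is None:
        timeline = simulate_percept_timeline(cfg, rng)
    rec, blinks = simulate_gaze(timeline, cfg, rng)
    keypresses, probes = simulate_keypresses_and_probes(timeline, cfg, rng, task)
    _, pupil, components = simulate_pupil(timeline, keypresses, cfg, rng)

    raw = cfg.pupil_baseline + cfg.pupil_gain * pupil
    pl = raw + rng.normal(0.0, 1.0, size=len(raw))
    pr = raw + rng.normal(0.0, 1.0, size=len(raw))
    lost = np.isnan(rec.xl)
    pl[lost] = np.nan
    pr[np.isnan(rec.xr)] = np.nan
    rec.pl, rec.pr = pl, pr

    truth = GroundTruth(
        timeline=timeline,
        keypress_times_ms=keypresses,
        probe_times_ms=probes,
        blink_intervals_ms=blinks,
        kernel_constriction=cfg.constriction_kernel(),
        kernel_dilation=cfg.dilation_kernel(),
        covariate_beta=cfg.covariate_beta,
        switch_amplitudes=components["switch_amplitudes"],
        pupil_components=components,
    )
    truth.validate()
    starts = np.array([t0 for t0, _ in cfg.trial_bounds_ms()])
    return SimulatedCondition(
        name=f"{stimulus}_{task}", stimulus=stimulus, task=task,
        recording=rec, truth=truth, trial_starts_ms=starts,
    )


def replay_switches(
    report_keypresses_ms: np.ndarray,
    directions: list[str],
    cfg: SimConfig,
    rt_s: float = 0.5,
) -> tuple[np.ndarray, list[str]]:
    """On-screen switch schedule: reported times shifted earlier by a fixed RT."""
    t = np.asarray(report_keypresses_ms, dtype=float) - rt_s * 1000.0
    keep = np.ones(len(t), dtype=bool)
    for i, ti in enumerate(t):
        inside = any(t0 < ti < t1 for t0, t1 in cfg.trial_bounds_ms())
        keep[i] = inside
    return t[keep], [d for d, k in zip(directions, keep) if k]


def simulate_observer(cfg: SimConfig, seed: int) -> dict[str, SimulatedCondition]:
    """All four conditions for one observer.

    Rivalry conditions draw independent gamma timelines; on-screen conditions
    replay the rivalry-report percept sequence (as reported via keypresses)
    shifted earlier by the fixed 500 ms reaction-time convention.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, SimulatedCondition] = {}
    out["rivalry_report"] = simulate_condition(cfg, rng, "rivalry", "report")
    out["rivalry_ignore"] = simulate_condition(cfg, rng, "rivalry", "ignore")

    rep = out["rivalry_report"]
    # directions of the presses mirror the reported switch directions
    sw = rep.truth.timeline
    dirs = [s.direction for s in sw.switches][: len(rep.truth.keypress_times_ms)]
    times, dirs = replay_switches(rep.truth.keypress_times_ms, dirs, cfg)
    # enforce alternation after the shift (drop any out-of-order stragglers)
    clean_t, clean_d = [], []
    for t, d in zip(times, dirs):
        if clean_t and (t <= clean_t[-1] or d == clean_d[-1]):
            continue
        clean_t.append(t)
        clean_d.append(d)
    replay_tl = timeline_from_switches(np.array(clean_t), clean_d, cfg.trial_bounds_ms())

    out["onscreen_report"] = simulate_condition(
        cfg, rng, "onscreen", "report", timeline=replay_tl)
    out["onscreen_ignore"] = simulate_condition(
        cfg, rng, "onscreen", "ignore", timeline=replay_tl)
    return out
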