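"""End-to-end orchestration: simulate -> decode -> preprocess -> GLM -> stats.

Two observer-level paths exist:

* the full chain (``condition_from_recording``) runs gaze cleaning, OKN
  decoding and pupil preprocessing on a raw-rate recording;
* the analysis-rate path (``simulate_glm_condition``) generates pupil traces
  directly on the 10 Hz grid with ground-truth events, for studies of the
  deconvolution and statistics stages where gaze decoding is not the object.

Condition order for the 2x2 repeated-measures ANOVA is
(rivalry_ignore, rivalry_report, onscreen_ignore, onscreen_report).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import cluster, gaze_events, glm, okn, pupil, synthetic
from .config import RunConfig, SimConfig
from .pupil import ConcatTrace
from .types import OcularEvent, PerceptTimeline

ANOVA_CONDITION_ORDER = (
    "rivalry_ignore", "rivalry_report", "onscreen_ignore", "onscreen_report",
)


# ---------------------------------------------------------------------------
# switch matching (decoder validation)
# ---------------------------------------------------------------------------

def match_switches(
    true_times_ms: np.ndarray,
    detected_times_ms: np.ndarray,
    tol_ms: float = 500.0,
) -> dict:
    """Greedy one-to-one matching of detected to true switches within a
    tolerance; reports hit rate and the false-alarm count (unmatched
    detections) as a fraction of the true count."""
    true_t = np.sort(np.asarray(true_times_ms, float))
    det_t = np.sort(np.asarray(detected_times_ms, float))
    used = np.zeros(len(det_t), dtype=bool)
    hits = 0
    for t in true_t:
        if len(det_t) == 0:
            break
        d = np.abs(det_t - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            used[j] = True
            hits += 1
    n_true = max(len(true_t), 1)
    return {
        "n_true": len(true_t),
        "n_detected": len(det_t),
        "hits": hits,
        "hit_rate": hits / n_true,
        "false_alarms": int(len(det_t) - used.sum()),
        "false_alarm_rate": (len(det_t) - int(used.sum())) / n_true,
    }


# ---------------------------------------------------------------------------
# per-condition analysis containers
# ---------------------------------------------------------------------------

@dataclass
class ConditionData:
    """Analysis-ready view of one observer-condition."""

    name: str
    stimulus: str
    task: str
    trace: ConcatTrace
    events: dict = field(default_factory=dict)


def following_durations_ms(timeline: PerceptTimeline) -> np.ndarray:
    """Duration of the dominance episode initiated by each switch."""
    starts = {ep.onset_ms: ep for ep in timeline.episodes}
    out = []
    for s in timeline.switches:
        ep = starts.get(s.time_ms)
        if ep is None:
            ep = min(timeline.episodes, key=lambda e: abs(e.onset_ms - s.time_ms))
        out.append(ep.duration_ms)
    return np.array(out)


def events_from_truth(sim: synthetic.SimulatedCondition) -> dict:
    tl = sim.truth.timeline
    return {
        "stimulus": sim.stimulus,
        "task": sim.task,
        "switch_times_ms": tl.switch_times,
        "switch_directions": list(tl.switch_directions),
        "preceding_dur_ms": synthetic.preceding_durations_ms(tl),
        "following_dur_ms": following_durations_ms(tl),
        "keypress_times_ms": np.asarray(sim.truth.keypress_times_ms, float),
        "probe_times_ms": np.asarray(sim.truth.probe_times_ms, float),
        "saccades": [],
        "blinks": [OcularEvent("blink", a, b)
                   for a, b in sim.truth.blink_intervals_ms],
        "trial_start_ms": sim.trial_starts_ms.astype(float),
    }


# ---------------------------------------------------------------------------
# full chain on a raw recording
# ---------------------------------------------------------------------------

def detect_ocular_events(
    rec, cfg: RunConfig
) -> tuple[list[OcularEvent], list[OcularEvent]]:
    """Binocular saccade and blink event lists for a recording."""
    sac_l, sac_r = gaze_events.detect_saccades_recording(
        rec, cfg.saccade_min_dur_ms, cfg.saccade_lambda_sd,
        cfg.min_segment_samples)
    saccades = gaze_events.binocular_merge(sac_l, sac_r)
    bl_l = gaze_events.detect_blinks_one_eye(
        rec.time_ms, np.isnan(rec.xl) | np.isnan(rec.yl))
    bl_r = gaze_events.detect_blinks_one_eye(
        rec.time_ms, np.isnan(rec.xr) | np.isnan(rec.yr))
    blinks = gaze_events.binocular_merge(bl_l, bl_r)
    return saccades, blinks


def decode_condition(
    sim: synthetic.SimulatedCondition, cfg: RunConfig | None = None
) -> tuple[PerceptTimeline, list[OcularEvent], list[OcularEvent]]:
    """Raw recording -> decoded percept timeline (+ saccades, blinks)."""
    cfg = cfg or RunConfig()
    rec = sim.recording
    saccades, blinks = detect_ocular_events(rec, cfg)
    clean = gaze_events.clean_gaze(
        rec, saccades, blinks, cfg.saccade_pad_ms, cfg.blink_pad_ms)
    timeline, _ = okn.decode_recording(clean, rec.trials, blinks, cfg)
    return timeline, saccades, blinks


def condition_from_recording(
    sim: synthetic.SimulatedCondition,
    cfg: RunConfig | None = None,
    use_true_switches: bool = False,
) -> ConditionData:
    """Full chain: ocular events, OKN decode, pupil preprocessing."""
    cfg = cfg or RunConfig()
    timeline, saccades, blinks = decode_condition(sim, cfg)
    trace = pupil.preprocess_recording(sim.recording, blinks, cfg)
    src = sim.truth.timeline if use_true_switches else timeline
    ev = events_from_truth(sim)
    ev.update({
        "switch_times_ms": src.switch_times,
        "switch_directions": list(src.switch_directions),
        "preceding_dur_ms": synthetic.preceding_durations_ms(src),
        "following_dur_ms": following_durations_ms(src),
        "saccades": saccades,
        "blinks": blinks,
    })
    return ConditionData(sim.name, sim.stimulus, sim.task, trace, ev)


# ---------------------------------------------------------------------------
# analysis-rate synthetic path
# ---------------------------------------------------------------------------

def _trace_10hz(
    timeline: PerceptTimeline,
    keypresses_ms: np.ndarray,
    cfg: SimConfig,
    run_cfg: RunConfig,
    rng: np.random.Generator,
) -> ConcatTrace:
    """Pupil trace generated directly on the analysis grid (kernel units),
    per-trial exponentially detrended, zeros between trials."""
    cfg10 = replace(cfg, sample_rate_hz=run_cfg.analysis_rate_hz)
    t_ms, raw, _ = synthetic.simulate_pupil(timeline, keypresses_ms, cfg10, rng)
    bin_ms = 1000.0 / run_cfg.analysis_rate_hz
    n = len(raw)
    values = np.zeros(n)
    trial_map = np.full(n, -1, dtype=int)
    for idx, (t0, t1) in enumerate(cfg.trial_bounds_ms()):
        i0, i1 = int(round(t0 / bin_ms)), min(int(round(t1 / bin_ms)), n)
        resid, _ = pupil.detrend_exponential(
            (t_ms[i0:i1] - t0) / 1000.0, raw[i0:i1],
            run_cfg.detrend_min_tau_s, run_cfg.detrend_max_tau_s)
        values[i0:i1] = resid
        trial_map[i0:i1] = idx
    return ConcatTrace(t_ms, values, trial_map, run_cfg.analysis_rate_hz)


def simulate_glm_condition(
    cfg: SimConfig,
    rng: np.random.Generator,
    stimulus: str = "rivalry",
    task: str = "report",
    run_cfg: RunConfig | None = None,
    timeline: PerceptTimeline | None = None,
) -> tuple[ConditionData, synthetic.GroundTruth]:
    """One condition generated at the analysis rate with true events."""
    run_cfg = run_cfg or RunConfig()
    if timeline is None:
        timeline = synthetic.simulate_percept_timeline(cfg, rng)
    keypresses, probes = synthetic.simulate_keypresses_and_probes(
        timeline, cfg, rng, task)
    trace = _trace_10hz(timeline, keypresses, cfg, run_cfg, rng)
    truth = synthetic.GroundTruth(
        timeline=timeline, keypress_times_ms=keypresses, probe_times_ms=probes,
        blink_intervals_ms=[], kernel_constriction=cfg.constriction_kernel(),
        kernel_dilation=cfg.dilation_kernel(), covariate_beta=cfg.covariate_beta,
    )
    ev = {
        "stimulus": stimulus, "task": task,
        "switch_times_ms": timeline.switch_times,
        "switch_directions": list(timeline.switch_directions),
        "preceding_dur_ms": synthetic.preceding_durations_ms(timeline),
        "following_dur_ms": following_durations_ms(timeline),
        "keypress_times_ms": keypresses, "probe_times_ms": probes,
        "saccades": [], "blinks": [],
        "trial_start_ms": np.array([t0 for t0, _ in cfg.trial_bounds_ms()]),
    }
    return ConditionData(f"{stimulus}_{task}", stimulus, task, trace, ev), truth


def simulate_glm_observer(
    cfg: SimConfig, seed: int, run_cfg: RunConfig | None = None
) -> dict[str, ConditionData]:
    """All four conditions on the analysis grid (true events, no gaze)."""
    rng = np.random.default_rng(seed)
    run_cfg = run_cfg or RunConfig()
    out = {}
    for stim in ("rivalry", "onscreen"):
        for task in ("ignore", "report"):
            cond, _ = simulate_glm_condition(cfg, rng, stim, task, run_cfg)
            out[f"{stim}_{task}"] = cond
    return out


# ---------------------------------------------------------------------------
# concatenation across conditions and model fitting
# ---------------------------------------------------------------------------

def concat_conditions(conds: list[ConditionData]) -> tuple[ConcatTrace, dict]:
    """Concatenate condition traces on one session axis; event times and
    trial indices are offset so streams stay distinct."""
    values, tmap, events = [], [], {}
    offset_ms = 0.0
    trial_offset = 0
    rate = conds[0].trace.rate_hz
    for cond in conds:
        tr = cond.trace
        values.append(tr.values)
        shifted = np.where(tr.trial_map >= 0, tr.trial_map + trial_offset, -1)
        tmap.append(shifted)
        ev = dict(cond.events)
        for key in ("switch_times_ms", "keypress_times_ms", "probe_times_ms",
                    "trial_start_ms"):
            ev[key] = np.asarray(ev[key], float) + offset_ms
        for key in ("saccades", "blinks"):
            ev[key] = [OcularEvent(e.kind, e.onset_ms + offset_ms,
                                   e.offset_ms + offset_ms, e.binocular)
                       for e in ev[key]]
        events[cond.name] = ev
        trial_offset += int(tr.trial_map.max()) + 1
        offset_ms += len(tr.values) * tr.bin_ms
    trace = ConcatTrace(
        np.arange(sum(len(v) for v in values)) * (1000.0 / rate),
        np.concatenate(values), np.concatenate(tmap), rate)
    return trace, events


def fit_observer(
    conds: list[ConditionData],
    mode: str,
    run_cfg: RunConfig | None = None,
    covariate_side: str | None = None,
    signal: str = "derivative",
) -> glm.GLMFit:
    """Concatenate an observer's conditions and fit the requested design."""
    run_cfg = run_cfg or RunConfig()
    trace, events = concat_conditions(conds)
    specs = glm.build_event_regressors(events, mode, run_cfg, covariate_side)
    design = glm.make_design(
        specs, len(trace.values), trace.trial_map, trace.bin_ms)
    y = pupil.derivative(trace).values if signal == "derivative" else trace.values
    return glm.fit_glm(y, design)


def _stack_curves(
    fits: list[glm.GLMFit], names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    lags = fits[0].curves[names[0]].lags_s
    arr = np.array([[f.curves[n].values for n in names] for f in fits])
    return lags, arr  # observers x regressors x lags


# ---------------------------------------------------------------------------
# study-level analyses
# ---------------------------------------------------------------------------

def run_switch_locked_analysis(
    observers: list[dict[str, ConditionData]],
    run_cfg: RunConfig | None = None,
    n_iter: int | None = None,
    seed: int = 0,
    signal: str = "derivative",
) -> dict:
    """Per-condition switch-locked response curves with one-sample cluster
    tests per condition and the 2x2 stimulus-by-task ANOVA across conditions."""
    run_cfg = run_cfg or RunConfig()
    n_iter = n_iter or run_cfg.n_permutations
    fits = [fit_observer([obs[c] for c in ANOVA_CONDITION_ORDER],
                         "per-condition", run_cfg, signal=signal)
            for obs in observers]
    names = [f"switch:{c}" for c in ANOVA_CONDITION_ORDER]
    lags, curves = _stack_curves(fits, names)
    results = {"lags_s": lags, "curves": curves, "clusters": {}}
    rng = np.random.default_rng(seed)
    for i, cond in enumerate(ANOVA_CONDITION_ORDER):
        results["clusters"][cond] = cluster.cluster_test(
            curves[:, i, :], lags, "one-sample", n_iter, rng,
            run_cfg.alpha_enter)["mean"]
    results["clusters"]["anova"] = cluster.cluster_test(
        curves, lags, "rm-anova-2x2", n_iter, rng, run_cfg.alpha_enter)
    return results


def run_pooled_analysis(
    observers: list[dict[str, ConditionData]],
    run_cfg: RunConfig | None = None,
    n_iter: int | None = None,
    seed: int = 0,
    signal: str = "derivative",
) -> dict:
    """Pooled switch-locked (rivalry / on-screen) and keypress-locked curves,
    with a paired cluster test between the two switch curves."""
    run_cfg = run_cfg or RunConfig()
    n_iter = n_iter or run_cfg.n_permutations
    fits = [fit_observer([obs[c] for c in ANOVA_CONDITION_ORDER],
                         "pooled", run_cfg, signal=signal)
            for obs in observers]
    names = ["switch:rivalry", "switch:onscreen", "keypress"]
    lags, curves = _stack_curves(fits, names)
    rng = np.random.default_rng(seed)
    results = {"lags_s": lags, "curves": curves, "names": names, "clusters": {}}
    for i, name in enumerate(names):
        results["clusters"][name] = cluster.cluster_test(
            curves[:, i, :], lags, "one-sample", n_iter, rng,
            run_cfg.alpha_enter)["mean"]
    results["clusters"]["rivalry_vs_onscreen"] = cluster.cluster_test(
        curves[:, :2, :], lags, "paired", n_iter, rng,
        run_cfg.alpha_enter)["difference"]
    return results


def run_duration_covariate_analysis(
    observers: list[dict[str, ConditionData]],
    side: str = "preceding",
    run_cfg: RunConfig | None = None,
    n_iter: int | None = None,
    seed: int = 0,
    signal: str = "derivative",
) -> dict:
    """Per-condition duration-covariate modulation curves with one-sample
    cluster tests and the 2x2 ANOVA on the modulation curves."""
    run_cfg = run_cfg or RunConfig()
    n_iter = n_iter or run_cfg.n_permutations
    fits = [fit_observer([obs[c] for c in ANOVA_CONDITION_ORDER],
                         "per-condition", run_cfg, covariate_side=side,
                         signal=signal)
            for obs in observers]
    names = [f"switch:{c}:dur_{side}" for c in ANOVA_CONDITION_ORDER]
    lags, curves = _stack_curves(fits, names)
    rng = np.random.default_rng(seed)
    results = {"lags_s": lags, "curves": curves, "clusters": {}}
    for i, cond in enumerate(ANOVA_CONDITION_ORDER):
        results["clusters"][cond] = cluster.cluster_test(
            curves[:, i, :], lags, "one-sample", n_iter, rng,
            run_cfg.alpha_enter)["mean"]
    results["clusters"]["anova"] = cluster.cluster_test(
        curves, lags, "rm-anova-2x2", n_iter, rng, run_cfg.alpha_enter)
    return results


def quantile_curves(
    conds: list[ConditionData],
    side: str = "preceding",
    k: int = 3,
    run_cfg: RunConfig | None = None,
    signal: str = "trace",
) -> dict:
    """Descriptive switch-locked curves per duration quantile, one observer."""
    run_cfg = run_cfg or RunConfig()
    trace, events = concat_conditions(conds)
    specs: list[glm.RegressorSpec] = []
    for cond, ev in events.items():
        groups = glm.quantile_split(
            ev["switch_times_ms"], ev[f"{side}_dur_ms"], k)
        for q, idx in enumerate(groups):
            specs.append(glm.RegressorSpec(
                f"switch:{cond}:q{q}", ev["switch_times_ms"][idx],
                run_cfg.switch_window_s))
    specs.append(glm.RegressorSpec(
        "trial_start",
        np.concatenate([ev["trial_start_ms"] for ev in events.values()]),
        (0.0, run_cfg.switch_window_s[1]), exclude_trial_edges=False))
    design = glm.make_design(specs, len(trace.values), trace.trial_map,
                             trace.bin_ms)
    y = pupil.derivative(trace).values if signal == "derivative" else trace.values
    fit = glm.fit_glm(y, design)
    return {name: c for name, c in fit.curves.items() if name != "trial_start"}
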