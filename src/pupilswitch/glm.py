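"""Event-related response estimation by linear deconvolution.

Two regression bases over a fixed peri-event window on the 10 Hz analysis
grid:

* ``fir`` — one free coefficient per 100 ms lag bin (classic deconvolution);
* ``fourier`` — an offset plus the sines and cosines needed to capture
  fluctuations at ``max_freq_hz`` and slower over the window, so a 10 s
  window at 1 Hz gives 1 + 2*10 = 21 terms (8 s -> 17, 5 s -> 11).

All regressors of a model are fit jointly by ordinary least squares over the
concatenated trace, which resolves temporally overlapping responses that
would bias event-locked averaging. Rank-deficient designs (possible in tiny
synthetic cases) get the minimum-norm solution.

Events may carry a per-event covariate (z-scored log dominance durations);
the covariate regressor's curve is then the modulation of the response per
covariate unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .types import OcularEvent, ResponseCurve


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

def lag_grid(window_s: tuple[float, float], step_s: float = 0.1) -> np.ndarray:
    start, end = window_s
    n = int(round((end - start) / step_s)) + 1
    return start + step_s * np.arange(n)


def fourier_basis(
    window_s: tuple[float, float],
    max_freq_hz: float = 1.0,
    step_s: float = 0.1,
) -> np.ndarray:
    """Fourier basis sampled on the window's lag grid.

    Columns: a constant, then sin/cos pairs at frequencies k / window-length
    for k = 1 .. floor(max_freq_hz * window-length). A window shorter than one
    period of ``max_freq_hz`` degenerates to the constant column.
    """
    start, end = window_s
    length = end - start
    if length <= 0:
        raise ValueError("window length must be positive")
    lags = lag_grid(window_s, step_s)
    n_pairs = int(np.floor(max_freq_hz * length + 1e-9))
    cols = [np.ones(len(lags))]
    phase = (lags - start) / length
    for k in range(1, n_pairs + 1):
        cols.append(np.sin(2 * np.pi * k * phase))
        cols.append(np.cos(2 * np.pi * k * phase))
    return np.column_stack(cols)


def fir_basis(window_s: tuple[float, float], step_s: float = 0.1) -> np.ndarray:
    return np.eye(len(lag_grid(window_s, step_s)))


# ---------------------------------------------------------------------------
# regressor specification and design matrix
# ---------------------------------------------------------------------------

@dataclass
class RegressorSpec:
    """One event stream entering the model."""

    name: str
    event_times_ms: np.ndarray
    window_s: tuple[float, float]
    basis: str = "fourier"          # "fourier" | "fir"
    max_freq_hz: float = 1.0
    step_s: float = 0.1
    covariate: np.ndarray | None = None   # per-event weights (else all ones)
    exclude_trial_edges: bool = True

    def basis_matrix(self) -> np.ndarray:
        if self.basis == "fourier":
            return fourier_basis(self.window_s, self.max_freq_hz, self.step_s)
        if self.basis == "fir":
            return fir_basis(self.window_s, self.step_s)
        raise ValueError(f"unknown basis {self.basis!r}")

    def lags_s(self) -> np.ndarray:
        return lag_grid(self.window_s, self.step_s)


@dataclass
class Design:
    X: np.ndarray
    specs: list[RegressorSpec]
    slices: list[slice]
    kept_events: list[np.ndarray]  # boolean per-event masks after edge exclusion
    columns: list[tuple[str, int]] = field(default_factory=list)


def make_design(
    specs: list[RegressorSpec],
    n_bins: int,
    trial_map: np.ndarray | None = None,
    bin_ms: float = 100.0,
) -> Design:
    """Stamp every regressor's basis at its event bins.

    With a trial map, events whose full window would extend beyond their
    trial (or that fall between trials) are excluded from regressors that
    request edge exclusion; regressors that do not (trial starts) have
    out-of-range rows clipped instead.
    """
    blocks, slices, kept, columns = [], [], [], []
    col0 = 0
    for spec in specs:
        basis = spec.basis_matrix()
        n_lags, n_terms = basis.shape
        offs = int(round(spec.window_s[0] / (bin_ms / 1000.0))) + np.arange(n_lags)
        Xb = np.zeros((n_bins, n_terms))
        bins = np.round(np.asarray(spec.event_times_ms, float) / bin_ms).astype(int)
        weights = (np.ones(len(bins)) if spec.covariate is None
                   else np.asarray(spec.covariate, float))
        keep = np.ones(len(bins), dtype=bool)
        for i, (b, w) in enumerate(zip(bins, weights)):
            rows = b + offs
            inside = (rows >= 0) & (rows < n_bins)
            if spec.exclude_trial_edges and trial_map is not None:
                ok = (
                    inside.all()
                    and 0 <= b < n_bins
                    and trial_map[b] >= 0
                    and np.all(trial_map[rows] == trial_map[b])
                )
                if not ok:
                    keep[i] = False
                    continue
                Xb[rows] += w * basis
            else:
                Xb[rows[inside]] += w * basis[inside]
        blocks.append(Xb)
        slices.append(slice(col0, col0 + n_terms))
        kept.append(keep)
        columns.extend((spec.name, k) for k in range(n_terms))
        col0 += n_terms
    X = np.concatenate(blocks, axis=1) if blocks else np.zeros((n_bins, 0))
    return Design(X, specs, slices, kept, columns)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    coefficients: np.ndarray
    curves: dict[str, ResponseCurve]
    design: Design

    def curve(self, name: str) -> ResponseCurve:
        return self.curves[name]


def fit_glm(trace_values: np.ndarray, design: Design) -> GLMFit:
    """Ordinary least squares of the concatenated trace on the design.

    Each regressor's response curve is its basis matrix times its
    coefficients; covariate regressors yield modulation curves (response
    change per covariate unit).
    """
    y = np.asarray(trace_values, float)
    if design.X.shape[0] != len(y):
        raise ValueError("design and trace length mismatch")
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    curves = {}
    for spec, sl in zip(design.specs, design.slices):
        curves[spec.name] = ResponseCurve(
            spec.name, spec.lags_s(), spec.basis_matrix() @ beta[sl])
    return GLMFit(beta, curves, design)


def fir_deconvolve(
    trace_values: np.ndarray,
    event_times_ms: np.ndarray,
    window_s: tuple[float, float],
    bin_ms: float = 100.0,
    trial_map: np.ndarray | None = None,
    name: str = "fir",
) -> ResponseCurve:
    """FIR least-squares deconvolution of one event stream (100 ms steps)."""
    if len(event_times_ms) == 0:
        raise ValueError("cannot deconvolve a regressor with zero events")
    spec = RegressorSpec(
        name, np.asarray(event_times_ms, float), window_s, basis="fir",
        step_s=bin_ms / 1000.0,
        exclude_trial_edges=trial_map is not None)
    design = make_design([spec], len(trace_values), trial_map, bin_ms)
    return fit_glm(trace_values, design).curves[name]


# ---------------------------------------------------------------------------
# duration covariates and quantile grouping
# ---------------------------------------------------------------------------

def duration_covariate(durations: np.ndarray) -> np.ndarray:
    """z-scored log dominance durations (mean 0, SD 1; all-equal -> zeros)."""
    d = np.asarray(durations, float)
    if np.any(d <= 0):
        raise ValueError("durations must be strictly positive")
    v = np.log(d)
    sd = v.std(ddof=0)
    return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd


def quantile_split(
    event_times_ms: np.ndarray, durations: np.ndarray, k: int = 3
) -> list[np.ndarray]:
    """Partition events into k near-equal groups by sorted duration.

    Sorting is by (duration, event time) so ties break by time order; with n
    not divisible by k the earlier (shorter-duration) groups take the extra
    events, e.g. n=10, k=3 -> sizes (4, 3, 3). Returns event-index arrays
    from shortest to longest durations.
    """
    t = np.asarray(event_times_ms, float)
    d = np.asarray(durations, float)
    if k > len(t):
        raise ValueError("more groups than events")
    order = np.lexsort((t, d))
    return [np.sort(g) for g in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# regressor building (study designs)
# ---------------------------------------------------------------------------

def merge_close_saccades(
    events: list[OcularEvent], max_gap_ms: float = 100.0
) -> list[OcularEvent]:
    """Merge saccade pairs fewer than ``max_gap_ms`` apart into one event
    (square-wave-jerk / saccadic-pulse consolidation)."""
    out: list[OcularEvent] = []
    for e in sorted(events, key=lambda e: e.onset_ms):
        if out and e.onset_ms - out[-1].offset_ms < max_gap_ms:
            prev = out[-1]
            out[-1] = OcularEvent(
                prev.kind, prev.onset_ms, max(prev.offset_ms, e.offset_ms),
                binocular=prev.binocular or e.binocular)
        else:
            out.append(e)
    return out


def filter_blink_events(
    events: list[OcularEvent],
    min_dur_ms: float = 130.0,
    max_dur_ms: float = 900.0,
) -> list[OcularEvent]:
    """Drop loss periods too brief or too long to be genuine blinks."""
    return [e for e in events if min_dur_ms <= e.duration_ms <= max_dur_ms]


def unreported_probes(
    probe_times_ms: np.ndarray,
    keypress_times_ms: np.ndarray,
    window_s: float = 2.0,
) -> np.ndarray:
    """Probes not followed by a keypress within ``window_s`` seconds."""
    probes = np.asarray(probe_times_ms, float)
    kp = np.sort(np.asarray(keypress_times_ms, float))
    if len(kp) == 0:
        return probes
    nxt = np.searchsorted(kp, probes, "left")
    has_report = (nxt < len(kp)) & (kp[np.minimum(nxt, len(kp) - 1)] - probes
                                    <= window_s * 1000.0)
    return probes[~has_report]


def build_event_regressors(
    condition_events: dict[str, dict],
    mode: str,
    cfg: RunConfig | None = None,
    covariate_side: str | None = None,
) -> list[RegressorSpec]:
    """Assemble the study's design-matrix regressors from event streams.

    ``condition_events[name]`` holds per-condition streams already on the
    concatenated time axis: ``switch_times_ms``, ``preceding_dur_ms``,
    ``following_dur_ms``, ``keypress_times_ms``, ``probe_times_ms``,
    ``saccades`` / ``blinks`` (OcularEvent lists), ``trial_start_ms``, and
    ``stimulus`` / ``task`` labels.

    mode "per-condition": one switch regressor per condition (plus shared
    trial-start, saccade and blink regressors, and keypress / unreported-probe
    regressors for ignore conditions). mode "pooled": switches pooled by
    stimulus class (rivalry vs on-screen) and a single keypress regressor
    across all conditions. ``covariate_side`` adds, per switch regressor, a
    parametric regressor weighted by the z-scored log preceding or following
    dominance duration.
    """
    cfg = cfg or RunConfig()
    specs: list[RegressorSpec] = []
    w_switch = cfg.switch_window_s

    def add_switch_regressor(name: str, times: np.ndarray, durs: np.ndarray | None):
        specs.append(RegressorSpec(name, times, w_switch))
        if covariate_side is not None:
            if durs is None or len(durs) != len(times):
                raise ValueError(f"missing {covariate_side} durations for {name}")
            specs.append(RegressorSpec(
                f"{name}:dur_{covariate_side}", times, w_switch,
                covariate=duration_covariate(durs)))

    if mode == "per-condition":
        for cond, ev in condition_events.items():
            durs = ev.get(f"{covariate_side}_dur_ms") if covariate_side else None
            add_switch_regressor(f"switch:{cond}", ev["switch_times_ms"], durs)
    elif mode == "pooled":
        for stim in ("rivalry", "onscreen"):
            times, durs = [], []
            for ev in condition_events.values():
                if ev["stimulus"] == stim:
                    times.append(ev["switch_times_ms"])
                    if covariate_side:
                        durs.append(ev[f"{covariate_side}_dur_ms"])
            if times:
                t = np.concatenate(times)
                d = np.concatenate(durs) if covariate_side else None
                add_switch_regressor(f"switch:{stim}", t, d)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # keypresses: ignore conditions only in the per-condition design, all
    # conditions pooled into one regressor in the pooled design
    kp = [ev["keypress_times_ms"] for ev in condition_events.values()
          if mode == "pooled" or ev["task"] == "ignore"]
    kp = [k for k in kp if len(k)]
    if kp:
        specs.append(RegressorSpec("keypress", np.concatenate(kp), w_switch))

    probes = []
    for ev in condition_events.values():
        if ev["task"] == "ignore" and len(ev.get("probe_times_ms", ())):
            probes.append(unreported_probes(
                ev["probe_times_ms"], ev["keypress_times_ms"],
                cfg.probe_report_window_s))
    if probes:
        specs.append(RegressorSpec(
            "unreported_probe", np.concatenate(probes), w_switch))

    starts = np.concatenate(
        [ev["trial_start_ms"] for ev in condition_events.values()])
    specs.append(RegressorSpec(
        "trial_start", starts, (0.0, w_switch[1]), exclude_trial_edges=False))

    saccades: list[OcularEvent] = []
    blinks: list[OcularEvent] = []
    for ev in condition_events.values():
        saccades.extend(ev.get("saccades", []))
        blinks.extend(ev.get("blinks", []))
    saccades = merge_close_saccades(saccades, cfg.saccade_merge_ms)
    blinks = filter_blink_events(blinks, cfg.blink_min_dur_ms, cfg.blink_max_dur_ms)
    if saccades:
        specs.append(RegressorSpec(
            "saccade", np.array([e.onset_ms for e in saccades]),
            cfg.saccade_window_s))
    if blinks:
        specs.append(RegressorSpec(
            "blink", np.array([e.onset_ms for e in blinks]),
            cfg.blink_window_s))
    return specs
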