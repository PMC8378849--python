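"""Pupil preprocessing: raw binocular area streams to the 10 Hz analysis
signal and its temporal derivative.

Fixed stage order: average eyes -> interpolate blinks -> per-trial
exponential detrend (time constant bounded below at 10 s) -> zero-phase
third-order Butterworth low-pass at 6 Hz -> per-trial z-score -> 10 Hz
bin-mean downsampling onto a concatenated session axis with exact zeros
between trials -> optional first-difference derivative (z/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt

from .config import RunConfig
from .types import GazeRecording, OcularEvent


@dataclass
class ConcatTrace:
    """Concatenated analysis-rate pupil trace with its trial map."""

    time_ms: np.ndarray
    values: np.ndarray
    trial_map: np.ndarray  # trial index per bin, -1 between trials
    rate_hz: float

    @property
    def bin_ms(self) -> float:
        return 1000.0 / self.rate_hz


def average_eyes(pl: np.ndarray, pr: np.ndarray) -> np.ndarray:
    """Per-sample mean of the eyes' pupil areas; one eye missing -> the other,
    both missing -> NaN (the sample belongs to a blink/loss run)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.vstack([pl, pr]), axis=0)


def interpolate_blinks(
    time_ms: np.ndarray,
    p: np.ndarray,
    blinks: list[OcularEvent],
    pre_ms: float = 50.0,
    post_ms: float = 85.0,
    flank_ms: float = 50.0,
) -> np.ndarray:
    """Linear interpolation across each blink window.

    Inside [onset - pre, offset + post] values lie on the straight line
    joining the mean pupil size over the ``flank_ms`` period before the
    window to the mean over the period after it; a window at a recording
    edge holds the available flank mean constant. Any remaining missing
    samples (loss not marked as a blink) are linearly interpolated.
    """
    out = p.copy()
    for b in sorted(blinks, key=lambda e: e.onset_ms):
        lo, hi = b.onset_ms - pre_ms, b.offset_ms + post_ms
        i0 = int(np.searchsorted(time_ms, lo, "left"))
        i1 = int(np.searchsorted(time_ms, hi, "right"))
        if i1 <= i0:
            continue
        left = p[np.searchsorted(time_ms, lo - flank_ms, "left"):i0]
        right = p[i1:np.searchsorted(time_ms, hi + flank_ms, "right")]
        left = left[~np.isnan(left)]
        right = right[~np.isnan(right)]
        if len(left) == 0 and len(right) == 0:
            continue
        a = left.mean() if len(left) else right.mean()
        c = right.mean() if len(right) else left.mean()
        out[i0:i1] = np.linspace(a, c, i1 - i0)
    bad = np.isnan(out)
    if np.any(bad) and np.any(~bad):
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def detrend_exponential(
    t_s: np.ndarray,
    p: np.ndarray,
    min_tau_s: float = 10.0,
    max_tau_s: float = 1000.0,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Subtract a fitted a*exp(-t/tau) + c from one trial's data, tau >= 10 s.

    The bound keeps the fit on slow drift rather than transient pupil events.
    Non-convergence falls back to a linear detrend (with a warning).
    Returns (residual, (a, tau, c)); the linear fallback reports tau = inf.
    """
    t = np.asarray(t_s, float) - t_s[0]
    model = lambda tt, a, tau, c: a * np.exp(-tt / tau) + c
    p0 = (p[0] - p[-1], max(min(t[-1], max_tau_s), min_tau_s), p[-1])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, p, p0=p0,
                bounds=([-np.inf, min_tau_s, -np.inf], [np.inf, max_tau_s, np.inf]),
                maxfev=5000,
            )
        return p - model(t, *popt), tuple(float(v) for v in popt)
    except (RuntimeError, ValueError):
        warnings.warn("exponential detrend failed; falling back to linear")
        coef = np.polyfit(t, p, 1)
        return p - np.polyval(coef, t), (float(coef[0]), float("inf"), float(coef[1]))


def lowpass_and_zscore(
    p: np.ndarray,
    sample_rate_hz: float,
    order: int = 3,
    cutoff_hz: float = 6.0,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, then z-score (mean 0, SD 1).

    Two-pass (forward-backward) filtering preserves event-locked latencies;
    the effective magnitude response is the squared single-pass response.
    """
    if sample_rate_hz <= 2 * cutoff_hz:
        raise ValueError("sample rate too low for the requested cutoff")
    pad = 3 * (order + 1) * 2
    if len(p) <= pad:
        raise ValueError("trial shorter than the filter warm-up")
    b, a = butter(order, cutoff_hz, fs=sample_rate_hz)
    f = filtfilt(b, a, p)
    sd = f.std(ddof=0)
    return (f - f.mean()) / sd if sd > 0 else f - f.mean()


def downsample_concat(
    trial_traces: list[tuple[float, np.ndarray]],
    sample_rate_hz: float,
    session_end_ms: float,
    out_hz: float = 10.0,
) -> ConcatTrace:
    """Bin-mean downsampling onto one concatenated session axis.

    ``trial_traces`` holds (trial_start_ms, z-scored samples) per trial. Bins
    between trials are exactly zero. Trial starts are snapped to the output
    grid.
    """
    bin_ms = 1000.0 / out_hz
    n_bins = int(np.ceil(session_end_ms / bin_ms))
    values = np.zeros(n_bins)
    trial_map = np.full(n_bins, -1, dtype=int)
    per_bin = int(round(sample_rate_hz / out_hz))
    if per_bin < 1:
        raise ValueError("output rate exceeds the sample rate")
    for trial_idx, (t0, z) in enumerate(trial_traces):
        b0 = int(round(t0 / bin_ms))
        n_full = len(z) // per_bin
        binned = z[: n_full * per_bin].reshape(n_full, per_bin).mean(axis=1)
        hi = min(b0 + n_full, n_bins)
        values[b0:hi] = binned[: hi - b0]
        trial_map[b0:hi] = trial_idx
    t = np.arange(n_bins) * bin_ms
    return ConcatTrace(t, values, trial_map, out_hz)


def derivative(trace: ConcatTrace) -> ConcatTrace:
    """Backward first difference scaled to per-second units (z/s)."""
    d = np.zeros_like(trace.values)
    d[1:] = np.diff(trace.values) * trace.rate_hz
    return ConcatTrace(trace.time_ms, d, trace.trial_map, trace.rate_hz)


def preprocess_recording(
    rec: GazeRecording,
    blinks: list[OcularEvent],
    cfg: RunConfig | None = None,
) -> ConcatTrace:
    """Full preprocessing chain for one recording (one condition block)."""
    cfg = cfg or RunConfig()
    p = average_eyes(rec.pl, rec.pr)
    p = interpolate_blinks(
        rec.time_ms, p, blinks,
        cfg.blink_interp_pre_ms, cfg.blink_interp_post_ms,
        cfg.blink_interp_flank_ms)
    trial_traces = []
    for t0, t1 in rec.trials:
        i0 = int(np.searchsorted(rec.time_ms, t0, "left"))
        i1 = int(np.searchsorted(rec.time_ms, t1, "left"))
        seg = p[i0:i1]
        t_s = (rec.time_ms[i0:i1] - t0) / 1000.0
        resid, _ = detrend_exponential(
            t_s, seg, cfg.detrend_min_tau_s, cfg.detrend_max_tau_s)
        z = lowpass_and_zscore(
            resid, rec.sample_rate_hz, cfg.butter_order, cfg.butter_cutoff_hz)
        trial_traces.append((t0, z))
    return downsample_concat(
        trial_traces, rec.sample_rate_hz, rec.trials[-1][1], cfg.analysis_rate_hz)
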