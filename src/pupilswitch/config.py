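"""Configuration objects for the simulator and the analysis chain.

Every tunable number of the pipeline lives in one of the two dataclasses
below so that a run is fully described by a config + a seed. Configs
round-trip through YAML bit-exactly (plain floats/ints/lists only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


def _kernel_grid(support_s: float, step_s: float = 0.1) -> np.ndarray:
    return np.round(np.arange(0.0, support_s + step_s / 2, step_s), 10)


def default_constriction_kernel(step_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Switch-locked pupil kernel: a rapid constriction peaking ~0.8 s after
    the perceptual switch, followed by a slower re-dilation past baseline.

    Built from smooth Gaussian lobes so it is effectively band-limited below
    1 Hz (matching the Fourier-basis window used to estimate it).
    """
    lags = _kernel_grid(6.0, step_s)
    v = -1.0 * np.exp(-0.5 * ((lags - 0.8) / 0.45) ** 2)
    v += 0.35 * np.exp(-0.5 * ((lags - 2.4) / 0.9) ** 2)
    return lags, v


def default_dilation_kernel(step_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Keypress-locked kernel: a dilation peaking ~1.2 s after the press with
    a slow return to baseline."""
    lags = _kernel_grid(6.0, step_s)
    v = 1.0 * np.exp(-0.5 * ((lags - 1.2) / 0.55) ** 2)
    v -= 0.30 * np.exp(-0.5 * ((lags - 3.2) / 1.0) ** 2)
    return lags, v


@dataclass
class SimConfig:
    """Ground-truth generator parameters.

    Defaults emulate the study conditions: 12 trials of 60 s per block,
    binocular tracking at 1000 Hz, gamma-distributed dominance durations with
    a ~3 s mean, probe onsets Uniform(3, 8) s apart, and report keypresses
    lagging switches by a few hundred milliseconds.
    """

    sample_rate_hz: float = 1000.0
    n_trials: int = 12
    trial_len_s: float = 60.0
    inter_trial_gap_s: float = 2.0

    # dominance dynamics: gamma durations, mean = shape * scale = 3 s
    dominance_gamma_shape: float = 3.0
    dominance_gamma_scale: float = 1.0

    # OKN mechanics (free parameters; the study records rather than models OKN)
    slow_phase_speed: float = 4.1       # screen units / s, matches dot speed
    quick_phase_interval_s: float = 0.6  # mean interval between resets
    quick_phase_dur_ms_range: tuple[float, float] = (20.0, 40.0)
    gaze_noise_sd: float = 0.02         # per-eye, per-sample position noise
                                        # (video-tracker RMS at 1000 Hz)

    # blinks: Poisson onsets, uniform durations (within the 130-900 ms band
    # that downstream regressor building treats as genuine blinks)
    blink_rate_hz: float = 0.2
    blink_dur_ms_range: tuple[float, float] = (150.0, 450.0)

    # report keypresses: truncated-normal reaction times (> 100 ms)
    rt_mean_s: float = 0.5
    rt_sd_s: float = 0.15
    rt_min_s: float = 0.1

    # ignore-task probes
    probe_interval_range_s: tuple[float, float] = (3.0, 8.0)
    probe_detect_prob: float = 0.8

    # pupil model; kernels are (lags_s, values) pairs on a 0.1 s grid,
    # None -> the package defaults below
    kernel_constriction: tuple | None = None
    kernel_dilation: tuple | None = None
    covariate_beta: float = 0.0   # constriction gain per z(log preceding duration)
    drift_amp: float = 1.5        # per-trial exponential drift amplitude
    drift_tau_s: float = 25.0
    noise_sd: float = 0.2
    pupil_baseline: float = 2000.0  # tracker units
    pupil_gain: float = 150.0       # tracker units per kernel unit

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sample_rate_hz", "trial_len_s", "dominance_gamma_shape",
            "dominance_gamma_scale", "slow_phase_speed",
            "quick_phase_interval_s", "rt_mean_s",
            "drift_tau_s", "pupil_gain",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        lo, hi = self.probe_interval_range_s
        if not lo < hi:
            raise ValueError("probe_interval_range_s must be increasing")
        if self.blink_rate_hz < 0 or self.noise_sd < 0 or self.rt_sd_s < 0:
            raise ValueError("rates and noise SDs must be non-negative")

    def constriction_kernel(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kernel_constriction is not None:
            lags, v = self.kernel_constriction
            return np.asarray(lags, float), np.asarray(v, float)
        return default_constriction_kernel()

    def dilation_kernel(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kernel_dilation is not None:
            lags, v = self.kernel_dilation
            return np.asarray(lags, float), np.asarray(v, float)
        return default_dilation_kernel()

    @property
    def trial_spacing_ms(self) -> float:
        return (self.trial_len_s + self.inter_trial_gap_s) * 1000.0

    def trial_bounds_ms(self) -> list[tuple[float, float]]:
        out = []
        for i in range(self.n_trials):
            t0 = i * self.trial_spacing_ms
            out.append((t0, t0 + self.trial_len_s * 1000.0))
        return out


@dataclass
class RunConfig:
    """Analysis-chain parameters (all stages)."""

    # gaze cleaning
    min_segment_samples: int = 5
    saccade_min_dur_ms: float = 6.0
    saccade_lambda_sd: float = 6.0
    saccade_pad_ms: float = 20.0
    blink_pad_ms: float = 50.0

    # OKN decoding
    okn_window_ms: float = 750.0
    okn_step_ms: float = 38.0
    okn_threshold: float = 0.85
    min_dominance_ms: float = 500.0
    blink_patch_pre_ms: float = 250.0
    blink_patch_post_ms: float = 400.0
    blink_patch_flank_ms: float = 100.0

    # pupil preprocessing
    blink_interp_pre_ms: float = 50.0
    blink_interp_post_ms: float = 85.0
    blink_interp_flank_ms: float = 50.0
    detrend_min_tau_s: float = 10.0
    detrend_max_tau_s: float = 1000.0
    butter_order: int = 3
    butter_cutoff_hz: float = 6.0
    analysis_rate_hz: float = 10.0

    # GLM windows (seconds relative to the event)
    switch_window_s: tuple[float, float] = (-3.5, 6.5)
    blink_window_s: tuple[float, float] = (-0.5, 7.5)
    saccade_window_s: tuple[float, float] = (-0.5, 4.5)
    fourier_max_freq_hz: float = 1.0
    fir_step_s: float = 0.1
    saccade_merge_ms: float = 100.0
    blink_min_dur_ms: float = 130.0
    blink_max_dur_ms: float = 900.0
    probe_report_window_s: float = 2.0

    # cluster statistics
    n_permutations: int = 1000
    alpha_enter: float = 0.05
    alpha_cluster: float = 0.01


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (list,)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _coerce(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def load_sim_config(path: str | Path) -> SimConfig:
    return _coerce(SimConfig, yaml.safe_load(Path(path).read_text()))


def load_run_config(path: str | Path) -> RunConfig:
    return _coerce(RunConfig, yaml.safe_load(Path(path).read_text()))


def config_hash(*cfgs) -> str:
    """Stable short hash identifying a parameterisation (stamped on outputs)."""
    payload = json.dumps([_to_plain(c) for c in cfgs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
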