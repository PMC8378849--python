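"""Core containers shared across the pipeline.

Times are milliseconds on the recording clock unless a name says otherwise;
response-curve lags are seconds. Perceptual states are the two exclusive
percepts, labelled ``"A"`` and ``"B"``; by convention A is the percept whose
slow-phase gaze drift is rightward (positive x) and B leftward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STATE_SIGN = {"A": 1.0, "B": -1.0}
OTHER_STATE = {"A": "B", "B": "A"}


@dataclass
class Episode:
    state: str
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Switch:
    time_ms: float
    direction: str  # the state that becomes dominant


@dataclass
class PerceptTimeline:
    """Alternating dominance episodes plus the switch moments between them."""

    episodes: list[Episode] = field(default_factory=list)
    switches: list[Switch] = field(default_factory=list)

    @property
    def switch_times(self) -> np.ndarray:
        return np.array([s.time_ms for s in self.switches], dtype=float)

    @property
    def switch_directions(self) -> list[str]:
        return [s.direction for s in self.switches]

    def state_at(self, t_ms: float) -> str | None:
        for ep in self.episodes:
            if ep.onset_ms <= t_ms < ep.offset_ms:
                return ep.state
        return None

    def validate(self) -> None:
        times = self.switch_times
        if np.any(np.diff(times) <= 0):
            raise ValueError("switch times must be strictly increasing")
        # alternation is required within a contiguous stretch of episodes;
        # across a coverage gap (a trial boundary) the state re-randomizes
        gaps = [
            (a.offset_ms, b.onset_ms)
            for a, b in zip(self.episodes, self.episodes[1:])
            if b.onset_ms > a.offset_ms
        ]
        for a, b in zip(self.switches, self.switches[1:]):
            gap_between = any(a.time_ms <= g0 and g1 <= b.time_ms
                              for g0, g1 in gaps)
            if a.direction == b.direction and not gap_between:
                raise ValueError("consecutive switches must alternate direction")
        for a, b in zip(self.episodes, self.episodes[1:]):
            if a.offset_ms > b.onset_ms:
                raise ValueError("episodes must not overlap")


@dataclass
class OcularEvent:
    """A saccade or blink interval, possibly merged across the two eyes."""

    kind: str  # "saccade" | "blink"
    onset_ms: float
    offset_ms: float
    binocular: bool = False

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class GazeRecording:
    """Binocular per-sample gaze + pupil streams with trial boundaries.

    Missing samples (tracker signal loss, blinks) are NaN, independently per
    eye. ``trials`` is a list of (start_ms, end_ms) on the same clock as
    ``time_ms``.
    """

    time_ms: np.ndarray
    xl: np.ndarray
    yl: np.ndarray
    pl: np.ndarray
    xr: np.ndarray
    yr: np.ndarray
    pr: np.ndarray
    trials: list[tuple[float, float]]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for name in ("xl", "yl", "pl", "xr", "yr", "pr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def missing_mask(self) -> np.ndarray:
        """True where either eye's gaze signal is lost."""
        left = np.isnan(self.xl) | np.isnan(self.yl)
        right = np.isnan(self.xr) | np.isnan(self.yr)
        return left | right


@dataclass
class ResponseCurve:
    """An event-locked time course on a uniform lag grid."""

    name: str
    lags_s: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None

    def peak_lag_s(self, sign: int = 0) -> float:
        v = self.values if sign == 0 else sign * self.values
        idx = int(np.argmax(np.abs(v) if sign == 0 else v))
        return float(self.lags_s[idx])

    def restricted(self, start_s: float, end_s: float) -> "ResponseCurve":
        keep = (self.lags_s >= start_s) & (self.lags_s <= end_s)
        return replace(
            self,
            lags_s=self.lags_s[keep],
            values=self.values[keep],
            se=None if self.se is None else self.se[keep],
        )


@dataclass
class ClusterResult:
    effect: str
    start_s: float
    end_s: float
    mass: float
    p: float
    sign: int  # +1 / -1 for t-maps, 0 for F-maps

    @property
    def significant(self) -> bool:
        return self.p < 0.01
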