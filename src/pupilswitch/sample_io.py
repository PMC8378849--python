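"""Text formats: the tabular sample format, event tables, timelines, curves.

The sample format is one row per sample, tab-separated, columns
``t_ms  xL  yL  pupilL  xR  yR  pupilR`` with ``NA`` marking signal loss,
plus a JSON sidecar holding trial boundaries, the sample rate and (for
synthetic data) the ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Episode, GazeRecording, OcularEvent, PerceptTimeline, Switch

SAMPLE_COLUMNS = ["t_ms", "xL", "yL", "pupilL", "xR", "yR", "pupilR"]


def write_recording(rec: GazeRecording, path: str | Path) -> None:
    df = pd.DataFrame({
        "t_ms": rec.time_ms, "xL": rec.xl, "yL": rec.yl, "pupilL": rec.pl,
        "xR": rec.xr, "yR": rec.yr, "pupilR": rec.pr,
    })
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.5f")


def read_recording(
    path: str | Path, trials: list[tuple[float, float]], sample_rate_hz: float
) -> GazeRecording:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample file lacks columns {missing}")
    return GazeRecording(
        time_ms=df["t_ms"].to_numpy(float),
        xl=df["xL"].to_numpy(float), yl=df["yL"].to_numpy(float),
        pl=df["pupilL"].to_numpy(float),
        xr=df["xR"].to_numpy(float), yr=df["yR"].to_numpy(float),
        pr=df["pupilR"].to_numpy(float),
        trials=trials, sample_rate_hz=sample_rate_hz,
    )


def write_sidecar(path: str | Path, rec: GazeRecording, truth=None) -> None:
    payload: dict = {
        "sample_rate_hz": rec.sample_rate_hz,
        "trials": [[a, b] for a, b in rec.trials],
    }
    if truth is not None:
        tl = truth.timeline
        payload["ground_truth"] = {
            "switch_times_ms": tl.switch_times.tolist(),
            "switch_directions": tl.switch_directions,
            "keypress_times_ms": np.asarray(truth.keypress_times_ms).tolist(),
            "probe_times_ms": np.asarray(truth.probe_times_ms).tolist(),
            "blink_intervals_ms": [[a, b] for a, b in truth.blink_intervals_ms],
            "covariate_beta": truth.covariate_beta,
            "kernel_constriction": [truth.kernel_constriction[0].tolist(),
                                    truth.kernel_constriction[1].tolist()],
            "kernel_dilation": [truth.kernel_dilation[0].tolist(),
                                truth.kernel_dilation[1].tolist()],
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_event_table(events: list[OcularEvent], path: str | Path) -> None:
    df = pd.DataFrame({
        "kind": [e.kind for e in events],
        "onset_ms": [e.onset_ms for e in events],
        "offset_ms": [e.offset_ms for e in events],
        "binocular": [int(e.binocular) for e in events],
    })
    df.to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> list[OcularEvent]:
    df = pd.read_csv(path, sep="\t")
    return [OcularEvent(r.kind, float(r.onset_ms), float(r.offset_ms),
                        bool(r.binocular)) for r in df.itertuples()]


def write_timeline(tl: PerceptTimeline, episodes_path, switches_path) -> None:
    pd.DataFrame({
        "state": [e.state for e in tl.episodes],
        "onset_ms": [e.onset_ms for e in tl.episodes],
        "offset_ms": [e.offset_ms for e in tl.episodes],
    }).to_csv(episodes_path, sep="\t", index=False)
    pd.DataFrame({
        "time_ms": [s.time_ms for s in tl.switches],
        "direction": [s.direction for s in tl.switches],
    }).to_csv(switches_path, sep="\t", index=False)


def read_timeline(episodes_path, switches_path) -> PerceptTimeline:
    eps = pd.read_csv(episodes_path, sep="\t")
    sws = pd.read_csv(switches_path, sep="\t")
    return PerceptTimeline(
        [Episode(r.state, float(r.onset_ms), float(r.offset_ms))
         for r in eps.itertuples()],
        [Switch(float(r.time_ms), r.direction) for r in sws.itertuples()],
    )


def write_curves(
    curves: dict[str, np.ndarray], lags_s: np.ndarray, path: str | Path,
    meta: dict | None = None,
) -> None:
    """Response curves as long-format TSV: regressor, lag_s, then one column
    per observer plus mean and SE."""
    rows = []
    for name, arr in curves.items():
        arr = np.atleast_2d(arr)  # observers x lags
        for j, lag in enumerate(lags_s):
            row = {"regressor": name, "lag_s": round(float(lag), 6),
                   "mean": arr[:, j].mean(),
                   "se": arr[:, j].std(ddof=1) / np.sqrt(arr.shape[0])
                         if arr.shape[0] > 1 else 0.0}
            for o in range(arr.shape[0]):
                row[f"obs{o}"] = arr[o, j]
            rows.append(row)
    df = pd.DataFrame(rows)
    if meta:
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        df.to_csv(path, sep="\t", index=False)
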