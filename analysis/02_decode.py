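"""Decode perceptual switches from the simulated recordings and validate.

Reads the sample files written by 01_simulate.py, runs the gaze-cleaning +
OKN decoding chain, and compares decoded switches against the ground truth:
per-condition hit rate within +/-500 ms, false-alarm rate, and the
correlation of per-condition switch counts (the synthetic analogue of
comparing switch-identification methods per observer).

Outputs under results/decode/: <condition>.episodes.tsv / .switches.tsv /
.events.tsv and validation.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pupilswitch import RunConfig, sample_io
from pupilswitch.pipeline import decode_condition, match_switches
from pupilswitch.synthetic import CONDITIONS, GroundTruth, SimulatedCondition
from pupilswitch.types import PerceptTimeline, Episode, Switch

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results" / "decode"


def load_condition(name: str) -> SimulatedCondition:
    side = sample_io.read_sidecar(SIM / f"{name}.truth.json")
    trials = [tuple(t) for t in side["trials"]]
    rec = sample_io.read_recording(SIM / f"{name}.samples.tsv", trials,
                                   side["sample_rate_hz"])
    gt = side["ground_truth"]
    switches = [Switch(t, d) for t, d in
                zip(gt["switch_times_ms"], gt["switch_directions"])]
    tl = PerceptTimeline(
        [Episode("A", a, b) for a, b in trials],  # episodes not needed here
        switches)
    truth = GroundTruth(
        timeline=tl,
        keypress_times_ms=np.array(gt["keypress_times_ms"]),
        probe_times_ms=np.array(gt["probe_times_ms"]),
        blink_intervals_ms=[tuple(b) for b in gt["blink_intervals_ms"]],
        kernel_constriction=tuple(map(np.array, gt["kernel_constriction"])),
        kernel_dilation=tuple(map(np.array, gt["kernel_dilation"])),
        covariate_beta=gt["covariate_beta"],
    )
    stim, task = name.split("_")
    return SimulatedCondition(name, stim, task, rec, truth,
                              np.array([t0 for t0, _ in trials]))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    rows = []
    for name in CONDITIONS:
        cond = load_condition(name)
        tl, saccades, blinks = decode_condition(cond, cfg)
        sample_io.write_timeline(tl, OUT / f"{name}.episodes.tsv",
                                 OUT / f"{name}.switches.tsv")
        sample_io.write_event_table(saccades + blinks,
                                    OUT / f"{name}.events.tsv")
        m = match_switches(cond.truth.timeline.switch_times, tl.switch_times)
        m["condition"] = name
        rows.append(m)
        print(f"{name}: hit rate {m['hit_rate']:.1%}, "
              f"false alarms {m['false_alarm_rate']:.1%} "
              f"({m['n_detected']} detected / {m['n_true']} true)")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "validation.tsv", sep="\t", index=False)
    r = np.corrcoef(df["n_true"], df["n_detected"])[0, 1]
    print(f"decoded vs true switch counts across conditions: r = {r:.3f}")


if __name__ == "__main__":
    main()
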