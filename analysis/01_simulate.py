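"""Simulate one observer's four-condition session and write the recordings.

Generates ground-truth-annotated gaze + pupil recordings (rivalry/on-screen
x report/ignore) in the tabular sample format with JSON sidecars, plus the
simulation config. Scaled to 6 trials of 60 s per condition so the whole
session writes in seconds.

Outputs under results/sim/: <condition>.samples.tsv, <condition>.truth.json,
sim_config.yaml.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pupilswitch import SimConfig, sample_io, synthetic
from pupilswitch.config import config_hash, save_config

SEED = 20260929
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_trials=6)
    save_config(cfg, OUT / "sim_config.yaml")
    observer = synthetic.simulate_observer(cfg, SEED)
    print(f"config hash {config_hash(cfg)}  seed {SEED}")
    for name, cond in observer.items():
        sample_io.write_recording(cond.recording, OUT / f"{name}.samples.tsv")
        sample_io.write_sidecar(OUT / f"{name}.truth.json",
                                cond.recording, cond.truth)
        tl = cond.truth.timeline
        print(f"{name}: {len(tl.switches)} switches, "
              f"{len(cond.truth.keypress_times_ms)} keypresses, "
              f"{len(cond.truth.blink_intervals_ms)} blinks")


if __name__ == "__main__":
    main()
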