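"""Preprocess the simulated pupil recordings to the 10 Hz analysis signal.

Reads the sample files from 01_simulate.py and the blink events from
02_decode.py, runs eye averaging, blink interpolation, exponential
detrending, 6 Hz low-pass filtering, per-trial z-scoring and 10 Hz
downsampling, and writes the concatenated trace per condition.

Outputs under results/prep/: <condition>.trace10hz.tsv.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

HERE = Path(__file__).resolve().parent
sys.path.insert(0, str(HERE.parent / "src"))

from pupilswitch import RunConfig, sample_io
from pupilswitch.pupil import preprocess_recording
from pupilswitch.synthetic import CONDITIONS

spec = importlib.util.spec_from_file_location("decode_step", HERE / "02_decode.py")
decode_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(decode_step)

DECODE = HERE.parent / "results" / "decode"
OUT = HERE.parent / "results" / "prep"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    for name in CONDITIONS:
        cond = decode_step.load_condition(name)
        events = sample_io.read_event_table(DECODE / f"{name}.events.tsv")
        blinks = [e for e in events if e.kind == "blink"]
        trace = preprocess_recording(cond.recording, blinks, cfg)
        pd.DataFrame({
            "t_ms": trace.time_ms,
            "z": trace.values,
            "trial": trace.trial_map,
        }).to_csv(OUT / f"{name}.trace10hz.tsv", sep="\t", index=False)
        in_trial = trace.trial_map >= 0
        print(f"{name}: {len(trace.values)} bins at 10 Hz, "
              f"{(~in_trial).sum()} zero-filled inter-trial bins, "
              f"per-bin SD {trace.values[in_trial].std():.3f}")


if __name__ == "__main__":
    main()
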