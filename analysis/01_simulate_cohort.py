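#!/usr/bin/env python
"""Simulate a demo subject and characterise the synthetic signals.

Generates one executing subject under the default protocol (2 x 50 cue-based
trials), writes a small demo recording (delimited + EDF) under scratch/, and
saves the ensemble-average MRCP per task — the simulated counterpart of the
grand-average movement-locked waveform — to results/ensemble_average_mrcp.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mrcpdetect import (SimulationConfig, generate_recording, io,
                        make_surrogate, resolve_onsets)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed)
    rec = generate_recording(cfg, "real", subject_id="demo")
    print(f"simulated subject: {len(rec.cue_times)} trials, "
          f"{rec.duration:.0f} s, fs_eeg={rec.fs_eeg} Hz")

    # small on-disk demo (2 trials/task) for format round-trips
    demo = generate_recording(cfg.replace(n_trials_per_task=2), "real", "demo")
    io.write_recording_delimited(demo, ROOT / "scratch" / "demo_recording")
    io.write_recording_edf(demo, ROOT / "scratch" / "demo_recording_edf" / "demo.edf")
    print("wrote demo recording under scratch/demo_recording[_edf]/")

    surrogate = make_surrogate(rec.eeg, rec.channels, rec.fs_eeg)
    resolved = resolve_onsets(rec)
    print(f"force onsets resolved for {len(resolved.onsets)} trials "
          f"({len(resolved.dropped)} dropped)")

    fs = rec.fs_eeg
    t = np.arange(-1000, 0) / fs
    table = {"time_s": t}
    for task in cfg.tasks:
        eps = []
        for i, onset in zip(resolved.trial_indices, resolved.onsets):
            if rec.task_labels[i] != task:
                continue
            j = int(round(onset * fs))
            eps.append(surrogate.temporal_path[j - 1000:j])
        avg = np.mean(eps, axis=0)
        table[f"{task}_uV"] = avg
        print(f"{task}: ensemble average of {len(eps)} epochs, "
              f"minimum {avg.min():.2f} µV at {t[np.argmin(avg)]:.2f} s")
    out = ROOT / "results" / "ensemble_average_mrcp.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(table).to_csv(out, index=False, float_format="%.4f")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
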