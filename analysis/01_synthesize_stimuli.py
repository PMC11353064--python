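#!/usr/bin/env python
"""Synthesize example trial audio for both experiments.

Writes one WAV (+ JSON event sidecar) per phase condition and experiment
under results/stimuli/, and a CSV of the phase -> target-onset geometry.
The geometry table is the quantity reused by the simulator: onsets are
spaced by a quarter of the 125 ms AM period and span exactly one period.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from echofit import StimulusSpec, assemble_trial_audio, phase_to_onset_delay, write_wav
from echofit.simulate import PHASE_CONDITIONS

OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for exp in (1, 2):
        spec = StimulusSpec.for_experiment(exp)
        for phase in PHASE_CONDITIONS:
            delay = phase_to_onset_delay(phase, spec)
            audio = assemble_trial_audio(440.0, phase, spec, seed=exp)
            name = f"exp{exp}_phase_{phase / np.pi:.2f}pi.wav"
            write_wav(audio, OUT / name)
            rows.append({
                "experiment": exp,
                "am_waveform": spec.am_waveform,
                "phase_rad": phase,
                "onset_delay_ms": delay * 1000,
                "target_dur_ms": spec.target_dur * 1000,
                "file": name,
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "onset_geometry.csv", index=False)
    print(table.to_string(index=False))
    for exp, grp in table.groupby("experiment"):
        spacing = np.diff(grp["onset_delay_ms"].to_numpy())
        print(f"experiment {exp}: onsets spaced by {spacing[0]:.2f} ms, "
              f"span {grp['onset_delay_ms'].max() - grp['onset_delay_ms'].min():.1f} ms")


if __name__ == "__main__":
    main()
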