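#!/usr/bin/env python
"""Score the SD session's EEG/EMG, validate against ground truth, quantify delta power.

Reads results/session_sd/, runs the rule-based epoch scorer, reports its
agreement with the generator's hypnogram, computes per-NREM-epoch delta
(2-4 Hz) power, and the recovery-over-baseline delta rebound.
"""

import json
from pathlib import Path

import pandas as pd

from vlpoca import Hypnogram, delta_rebound, nrem_delta_power, score_hypnogram
from vlpoca.timeline import SessionTimeline

RESULTS = Path(__file__).resolve().parents[1] / "results"
EEG_FS = 100.0


def main() -> None:
    sess = RESULTS / "session_sd"
    eeg = pd.read_csv(sess / "eeg.csv")["value"].to_numpy()
    emg = pd.read_csv(sess / "emg.csv")["value"].to_numpy()
    truth = Hypnogram.read_csv(sess / "hypnogram.csv")
    timeline = SessionTimeline.from_json(sess / "timeline.json")

    scored = score_hypnogram(eeg, emg, EEG_FS)
    agreement = scored.agreement(truth)
    scored.write_csv(RESULTS / "hypnogram_scored.csv")
    print(f"scorer vs ground truth: {100 * agreement:.1f}% of {truth.n_epochs} epochs")

    delta = nrem_delta_power(eeg, EEG_FS, scored, timeline)
    delta.to_csv(RESULTS / "delta.csv", index=False)
    rebound = delta_rebound(delta)
    print(
        f"NREM delta power: baseline n={sum(delta.segment == 'baseline')} epochs, "
        f"recovery n={sum(delta.segment == 'recovery')} epochs; "
        f"rebound {rebound:.1f}% of baseline"
    )

    with open(RESULTS / "scoring_report.json", "w") as fh:
        json.dump(
            {"agreement": agreement, "delta_rebound_pct": rebound,
             "n_epochs": truth.n_epochs},
            fh,
            indent=1,
        )


if __name__ == "__main__":
    main()
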