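#!/usr/bin/env python
"""Group activity responses of the SD session across baseline, SD, and recovery.

Classifies the SD session's units from its baseline segment, maps the
analysis conditions (state-matched baseline/recovery epochs, imaged SD
windows), computes per-group mean ± SEM responses with the Friedman/SNK and
Wilcoxon battery, and reports the directional findings.
"""

from pathlib import Path

import pandas as pd

from vlpoca import Hypnogram, analyze_sd_session
from vlpoca.preprocess import read_traces_csv
from vlpoca.synth import Session, SimConfig
from vlpoca.timeline import SessionTimeline

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_session(path: Path) -> Session:
    import json

    import numpy as np

    traces = read_traces_csv(path / "traces.csv")
    hyp = Hypnogram.read_csv(path / "hypnogram.csv")
    tl = SessionTimeline.from_json(path / "timeline.json")
    meta = pd.read_csv(path / "metadata.csv")
    truth = json.loads((path / "ground_truth.json").read_text())
    return Session(
        cfg=SimConfig(),
        hypnogram=hyp,
        timeline=tl,
        traces=traces,
        ground_truth=truth,
        eeg=np.zeros(0),
        emg=np.zeros(0),
        metadata=meta,
    )


def main() -> None:
    session = load_session(RESULTS / "session_sd")
    res = analyze_sd_session(session)

    res["responses"].to_csv(RESULTS / "responses.tsv", sep="\t", index=False)
    res["stats"].to_csv(RESULTS / "responses_stats.tsv", sep="\t", index=False)

    means = res["means"]
    print("group x condition mean ΔF/F₀:")
    print(means.round(3).to_string())

    sa, wa = means.loc["sleep-active"], means.loc["wake-active"]
    print(
        f"\nsleep-active: SD_h3 / baseline-AW = "
        f"{100 * sa['SD_h3'] / sa['baseline-AW']:.0f}% "
        f"(activity rises as pressure builds)"
    )
    print(
        f"wake-active: recovery-AW / baseline-AW = "
        f"{100 * wa['recovery-AW'] / wa['baseline-AW']:.0f}%"
    )
    wil = res["stats"].query("test == 'wilcoxon'")
    print("\nWilcoxon contrasts (per group):")
    print(wil.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
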