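#!/usr/bin/env python
"""Condition the spontaneous-session traces into a quality-filtered epoch matrix.

Reads results/session_spontaneous/, aligns the 10 Hz ΔF/F₀ traces to the
hypnogram, averages them into 10 s epochs, applies the <0.5 mean-intensity
quality cut, and writes results/epochs_spontaneous.csv plus a removal log.
"""

from pathlib import Path

from vlpoca import Hypnogram, quality_filter, state_means
from vlpoca.preprocess import epoch_matrix, read_traces_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sess = RESULTS / "session_spontaneous"
    traces = read_traces_csv(sess / "traces.csv")
    hyp = Hypnogram.read_csv(sess / "hypnogram.csv")

    em = epoch_matrix(traces, hyp)
    sm = state_means(em, hyp)
    kept, removed = quality_filter(sm, threshold=0.5)

    em[kept].to_csv(RESULTS / "epochs_spontaneous.csv", index_label="epoch_index")
    removed.to_csv(RESULTS / "quality_removed.csv")
    print(f"epoched {em.shape[1]} units into {len(em)} epochs; kept {len(kept)}")
    if len(removed):
        print("removed (mean state intensity < 0.5):")
        print(removed["mean_across_states"].round(3).to_string())
    else:
        print("no units fell below the quality threshold")


if __name__ == "__main__":
    main()
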