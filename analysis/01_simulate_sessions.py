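#!/usr/bin/env python
"""Generate the two synthetic sessions the downstream analyses use.

Writes a 90-min spontaneous-sleep session (100 units) and a 5-h
sleep-deprivation session (46 units: 1 h baseline, 3 h enforced wake with
the last 10 min of each hour imaged, 1 h recovery) under results/.
"""

from pathlib import Path

from vlpoca import SimConfig, simulate_session, write_session
from vlpoca.synth import default_phenotype_counts

RESULTS = Path(__file__).resolve().parents[1] / "results"

SD_COUNTS = {
    "nonREMS/REMS-max": 14,
    "nonREMS-max": 4,
    "REMS-active": 5,
    "wake-max": 16,
    "wake/REMS-max": 3,
    "state-indifferent": 4,
}


def main() -> None:
    cfg = SimConfig()

    spont = simulate_session(
        cfg, 11, paradigm="spontaneous", duration_s=5400.0,
        phenotype_counts=default_phenotype_counts(100),
    )
    write_session(spont, RESULTS / "session_spontaneous")
    print(
        f"spontaneous session: {spont.traces.shape[1]} units, "
        f"{spont.hypnogram.n_epochs} epochs, states {spont.hypnogram.state_counts()}"
    )

    sd = simulate_session(cfg, 12, paradigm="sd", phenotype_counts=SD_COUNTS)
    write_session(sd, RESULTS / "session_sd")
    p = sd.timeline.pressure
    print(
        f"SD session: {sd.traces.shape[1]} units, {sd.hypnogram.n_epochs} epochs; "
        f"pressure {p[0]:.2f} -> {p[1440]:.2f} (end of SD) -> {p[-1]:.2f} (end of recovery)"
    )


if __name__ == "__main__":
    main()
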