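"""Shared fixtures: the fixed-seed synthetic sessions used across the suite.

Session-scoped so that the (relatively expensive) simulations run once.
"""

import pytest

from vlpoca import SimConfig, simulate_session
from vlpoca.synth import default_phenotype_counts

#: Seed of the fixed synthetic suite.
SUITE_SEED = 42

#: Phenotype mix of the SD-paradigm sessions (46 units keeps them quick).
SD_COUNTS = {
    "nonREMS/REMS-max": 14,
    "nonREMS-max": 4,
    "REMS-active": 5,
    "wake-max": 16,
    "wake/REMS-max": 3,
    "state-indifferent": 4,
}


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def spont_session(cfg):
    """100 units, 90 min of spontaneous cycling, EEG/EMG included."""
    return simulate_session(
        cfg,
        SUITE_SEED,
        paradigm="spontaneous",
        duration_s=5400.0,
        phenotype_counts=default_phenotype_counts(100),
    )


@pytest.fixture(scope="session")
def sd_session(cfg):
    """Full SD paradigm (1 h baseline, 3 h SD, 1 h recovery), 46 units."""
    return simulate_session(cfg, 5, paradigm="sd", phenotype_counts=SD_COUNTS)


@pytest.fixture(scope="session")
def sd_analysis(sd_session):
    from vlpoca import analyze_sd_session

    return analyze_sd_session(sd_session)
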