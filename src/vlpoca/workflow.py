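"""End-to-end convenience workflows tying the pipeline stages together.

These are the canonical orderings of the pipeline stages — simulate/load,
epoch, profile, classify, segment, respond — used by the analysis scripts,
the validation suite, and any caller that wants one-call session analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify_units, state_activity_profiles
from .config import CATEGORY_OF, ClassifierThresholds, ScoringConfig, SimConfig
from .homeostatic import group_state_response, segment_sd_session
from .hypnogram import Hypnogram
from .preprocess import epoch_matrix
from .scoring import delta_rebound, nrem_delta_power, score_hypnogram
from .synth import Session

__all__ = [
    "classify_session",
    "phenotype_recovery",
    "scorer_agreement",
    "session_delta_rebound",
    "analyze_sd_session",
]


def classify_session(
    session: Session,
    thresholds: ClassifierThresholds | None = None,
    segment: str | None = "baseline",
) -> tuple:
    """Epoch, profile, and classify a session's units.

    Profiling is restricted to the epochs of `segment` (phenotypes are
    defined from spontaneous baseline sleep-wake activity); pass
    ``segment=None`` to use the whole session.  Returns
    `(epoch_matrix, profiles, calls)` where the epoch matrix covers the whole
    session.
    """
    em = epoch_matrix(session.traces, session.hypnogram, session.cfg.frame_rate)
    if segment is not None and segment in session.timeline.labels:
        idx = session.timeline.epochs_in(segment)
        idx = idx[idx < len(em)]
        sub_hyp = Hypnogram(
            session.hypnogram.states[idx], epoch_s=session.hypnogram.epoch_s
        )
        profiles = state_activity_profiles(em.iloc[idx].reset_index(drop=True), sub_hyp)
    else:
        profiles = state_activity_profiles(em, session.hypnogram)
    calls = classify_units(profiles, thresholds, metadata=session.metadata)
    return em, profiles, calls


def phenotype_recovery(
    session: Session, thresholds: ClassifierThresholds | None = None
) -> dict:
    """Fraction of units whose assigned phenotype the classifier recovers.

    Category recovery compares the broad class (sleep-active / wake-active /
    state-indifferent); subtype recovery compares the full subtype label.
    """
    _, _, calls = classify_session(session, thresholds)
    truth = session.ground_truth
    cat_hits, sub_hits = [], []
    for uid in calls.index:
        want = truth[uid]
        got_cat = calls.loc[uid, "category"]
        got_sub = (
            "state-indifferent"
            if got_cat == "state-indifferent"
            else calls.loc[uid, "subtype"]
        )
        cat_hits.append(got_cat == CATEGORY_OF[want])
        sub_hits.append(got_sub == want)
    return {
        "category": float(np.mean(cat_hits)),
        "subtype": float(np.mean(sub_hits)),
        "n": len(cat_hits),
        "calls": calls,
    }


def scorer_agreement(session: Session, scoring_cfg: ScoringConfig | None = None) -> float:
    """Epoch agreement of the rule-based scorer with the generator's hypnogram."""
    scored = score_hypnogram(session.eeg, session.emg, session.cfg.eeg_fs, scoring_cfg)
    return scored.agreement(session.hypnogram)


def session_delta_rebound(session: Session, scoring_cfg: ScoringConfig | None = None) -> float:
    """Recovery-over-baseline NREM delta power (%) from the session's EEG."""
    series = nrem_delta_power(
        session.eeg, session.cfg.eeg_fs, session.hypnogram, session.timeline, scoring_cfg
    )
    return delta_rebound(series)


def analyze_sd_session(
    session: Session,
    thresholds: ClassifierThresholds | None = None,
    cv_max: float | None = None,
) -> dict:
    """Full sleep-deprivation analysis of one session.

    Classifies units from the baseline segment, maps the SD conditions, and
    computes the per-group responses with statistics.  Returns a dict with
    `em`, `profiles`, `calls`, `condition_sets`, `responses`, `stats`,
    `unit_means`, and the group x condition `means` pivot.
    """
    em, profiles, calls = classify_session(session, thresholds)
    sets = segment_sd_session(session.timeline, session.hypnogram)
    responses, stats, unit_means = group_state_response(em, calls, sets, cv_max=cv_max)
    means = responses.pivot(index="group", columns="condition", values="mean")
    return {
        "em": em,
        "profiles": profiles,
        "calls": calls,
        "condition_sets": sets,
        "responses": responses,
        "stats": stats,
        "unit_means": unit_means,
        "means": means,
    }
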