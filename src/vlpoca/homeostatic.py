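"""Group responses to sleep deprivation across baseline, SD hours, and recovery.

Sessions are segmented into analysis conditions: state-matched epochs of the
baseline and recovery segments, and the imaged last-10-minute window of each
SD hour (wake epochs only; one-epoch sleep attempts are excluded from the
wake means and counted separately).  Per-unit condition means are averaged
within each phenotype group (mean ± SEM), and the condition profile is
tested with the Friedman/SNK battery plus Wilcoxon signed-rank contrasts of
recovery versus state-matched baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram
from .stats import friedman_ranks, snk_posthoc_ranks, wilcoxon_signed_rank
from .timeline import SessionTimeline

__all__ = ["segment_sd_session", "group_state_response", "CONDITION_ORDER"]

CONDITION_ORDER = [
    "baseline-AW",
    "baseline-QW",
    "baseline-NREM",
    "baseline-REM",
    "SD_h1",
    "SD_h2",
    "SD_h3",
    "recovery-AW",
    "recovery-NREM",
    "recovery-REM",
]

#: Wilcoxon contrasts of recovery (and late-SD) conditions vs baseline.
_PAIRED_CONTRASTS = [
    ("SD_h3", "baseline-AW"),
    ("recovery-AW", "baseline-AW"),
    ("recovery-NREM", "baseline-NREM"),
    ("recovery-REM", "baseline-REM"),
]


def segment_sd_session(timeline: SessionTimeline, hypnogram: Hypnogram) -> dict:
    """Map analysis conditions to epoch-index sets.

    Baseline and recovery conditions are state-matched within their
    segments; SD_hN holds the wake epochs of that hour's imaged window.
    Sleep-attempt epochs (NREM/REM during SD) are returned under
    "SD_hN-attempts".  Conditions with no epochs are omitted (with a warning
    for empty recovery states).
    """
    if "baseline" not in timeline.labels:
        raise ValueError("timeline lacks a baseline segment")
    uncovered = np.flatnonzero(timeline.epoch_labels(hypnogram.n_epochs) == "")
    if uncovered.size:
        raise ValueError(f"{uncovered.size} epochs not covered by any timeline segment")

    states = hypnogram.states
    out: dict = {}
    for seg_label, cond_states in (
        ("baseline", ("AW", "QW", "NREM", "REM")),
        ("recovery", ("AW", "NREM", "REM")),
    ):
        if seg_label not in timeline.labels:
            continue
        idx = timeline.epochs_in(seg_label)
        idx = idx[idx < hypnogram.n_epochs]
        for s in cond_states:
            sel = idx[states[idx] == s]
            if sel.size:
                out[f"{seg_label}-{s}"] = sel
            elif seg_label == "recovery":
                warnings.warn(f"no {s} epochs in recovery; condition omitted")

    for label in sorted(l for l in timeline.labels if l.startswith("SD_h")):
        idx = timeline.epochs_in(label, imaged_only=True)
        idx = idx[idx < hypnogram.n_epochs]
        wake = idx[np.isin(states[idx], ("AW", "QW"))]
        attempts = idx[~np.isin(states[idx], ("AW", "QW"))]
        if wake.size:
            out[label] = wake
        if attempts.size:
            out[f"{label}-attempts"] = attempts
    return out


def _condition_means(em: pd.DataFrame, condition_sets: dict) -> pd.DataFrame:
    conds = [c for c in CONDITION_ORDER if c in condition_sets]
    return pd.DataFrame(
        {c: em.iloc[condition_sets[c]].mean(axis=0) for c in conds}
    )


def group_state_response(
    em: pd.DataFrame,
    calls: pd.DataFrame,
    condition_sets: dict,
    cv_max: float | None = None,
) -> tuple:
    """Per-group condition means with the nonparametric test battery.

    Returns `(responses, stats, unit_means)`:

    * `responses` — rows (group, condition, n_units, mean, sem);
    * `stats` — Friedman across conditions within each group plus Wilcoxon
      signed-rank contrasts of recovery/late-SD vs baseline;
    * `unit_means` — the per-unit condition means (with group and an
      `excluded_unstable` flag when a coefficient-of-variation ceiling
      `cv_max` over baseline condition means is applied).
    """
    missing = [u for u in calls.index if u not in em.columns]
    if missing:
        raise ValueError(f"units missing from epoch matrix: {missing}")

    um = _condition_means(em, condition_sets)
    um = um.loc[calls.index]
    um.insert(0, "group", calls["category"])

    um["excluded_unstable"] = False
    if cv_max is not None:
        base_cols = [c for c in um.columns if str(c).startswith("baseline-")]
        base = um[base_cols]
        cv = base.std(axis=1) / base.mean(axis=1).abs()
        um.loc[cv > cv_max, "excluded_unstable"] = True

    work = um[~um["excluded_unstable"]]
    cond_cols = [c for c in um.columns if c in CONDITION_ORDER]

    resp_rows, stat_rows = [], []
    for group, grp in work.groupby("group", sort=True):
        vals = grp[cond_cols]
        for c in cond_cols:
            v = vals[c].dropna()
            resp_rows.append(
                {
                    "group": group,
                    "condition": c,
                    "n_units": len(v),
                    "mean": v.mean(),
                    "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                }
            )
        complete = vals.dropna(axis=0)
        if len(complete) >= 2 and complete.shape[1] >= 3:
            fr = friedman_ranks(complete.to_numpy())
            stat_rows.append(
                {
                    "group": group,
                    "test": "friedman",
                    "contrast": " vs ".join(cond_cols),
                    "statistic": fr.statistic,
                    "pvalue": fr.pvalue,
                    "n": fr.n,
                }
            )
            snk = snk_posthoc_ranks(complete.to_numpy(), labels=cond_cols)
            for _, r in snk[snk["significant"]].iterrows():
                stat_rows.append(
                    {
                        "group": group,
                        "test": "snk",
                        "contrast": f"{r['a']} vs {r['b']}",
                        "statistic": r["q"],
                        "pvalue": np.nan,
                        "n": len(complete),
                    }
                )
        for a, b in _PAIRED_CONTRASTS:
            if a in vals.columns and b in vals.columns:
                pair = vals[[a, b]].dropna()
                if len(pair) >= 2:
                    wt = wilcoxon_signed_rank(pair[a].to_numpy(), pair[b].to_numpy())
                    stat_rows.append(
                        {
                            "group": group,
                            "test": "wilcoxon",
                            "contrast": f"{a} vs {b}",
                            "statistic": wt.statistic,
                            "pvalue": wt.pvalue,
                            "n": wt.n,
                        }
                    )

    responses = pd.DataFrame(resp_rows)
    stats = pd.DataFrame(
        stat_rows, columns=["group", "test", "contrast", "statistic", "pvalue", "n"]
    )
    return responses, stats, um
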