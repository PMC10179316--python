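"""Phenotype classification of units from their state-activity profiles.

Each unit's per-state mean ΔF/F₀ (over *all* epochs of each state in the
session) yields three ratios: r_NA = NREM/AW, r_RA = REM/AW and
r_RN = REM/NREM.  The classifier applies the >=25% change criterion in a
fixed decision order:

1. REM-active          if r_RA > 2.0 and r_RN > 2.0
2. nonREM-sleep-active if r_NA > 1.25
     subtype nonREMS/REMS-max if r_RN > 0.5 (REM retains >=50% of NREM
     activity) else nonREMS-max
3. wake-active         if r_NA < 0.75
     subtype wake/REMS-max if 0.75 < r_RA < 2.0 else wake-max
4. state-indifferent   otherwise (all means within +/-25% of the AW mean)

REM-active precedes the nonREM rule because REM-active units may also show
NREM/AW > 1.25.  Strength grades express the fold change relative to the
lower state mean: weak 25-50%, moderate >50-100%, strong >100%.  Each
threshold rule can be validated post hoc with a logistic regression of class
membership on its ratio(s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import STATES, ClassifierThresholds
from .hypnogram import Hypnogram

__all__ = [
    "state_activity_profiles",
    "classify_call",
    "classify_units",
    "grade_strength",
    "tabulate_census",
    "aggregate_census",
    "census_percentages",
    "logistic_validation",
    "LogisticValidationResult",
    "SUBTYPE_COLUMNS",
]

SUBTYPE_COLUMNS = (
    "nonREMS/REMS-max",
    "nonREMS-max",
    "REMS-active",
    "wake-max",
    "wake/REMS-max",
    "state-indifferent",
)


# ---------------------------------------------------------------------------
# Profiles


def state_activity_profiles(em: pd.DataFrame, hypnogram: Hypnogram) -> pd.DataFrame:
    """Per-unit state means, classification ratios, and epoch counts.

    Means are taken over all epochs of each state.  Units lacking AW (or
    with a zero denominator) get NaN ratios and are later reported as
    unclassifiable; a missing REM state leaves r_RA/r_RN NaN.
    """
    n = len(em)
    states = hypnogram.states[:n]
    rows = {}
    for s in STATES:
        mask = states == s
        rows[f"m_{s}"] = (
            em.iloc[mask].mean(axis=0) if mask.any() else pd.Series(np.nan, index=em.columns)
        )
        rows[f"n_{s}"] = pd.Series(int(mask.sum()), index=em.columns)
    prof = pd.DataFrame(rows)

    def ratio(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = prof[num] / prof[den]
        return r.where((prof[den] > 0) & np.isfinite(r))

    prof["r_NA"] = ratio("m_NREM", "m_AW")
    prof["r_RA"] = ratio("m_REM", "m_AW")
    prof["r_RN"] = ratio("m_REM", "m_NREM")
    prof.index.name = "unit_id"
    return prof


# ---------------------------------------------------------------------------
# Classification


def classify_call(
    r_NA: float, r_RA: float, r_RN: float, thresholds: ClassifierThresholds | None = None
) -> tuple:
    """Apply the decision-order rules to one unit's ratios.

    Returns `(category, subtype)`; `("unclassifiable", "none")` when any
    ratio is undefined.  The ratios are scale-free, so the call is invariant
    to any positive rescaling of the unit's trace.
    """
    t = (thresholds or ClassifierThresholds()).validate()
    if not (np.isfinite(r_NA) and np.isfinite(r_RA) and np.isfinite(r_RN)):
        return "unclassifiable", "none"
    if r_RA > t.rem_cut and r_RN > t.rem_cut:
        return "sleep-active", "REMS-active"
    if r_NA > t.sleep_cut:
        subtype = "nonREMS/REMS-max" if r_RN > t.rem_retention_cut else "nonREMS-max"
        return "sleep-active", subtype
    if r_NA < t.wake_cut:
        subtype = "wake/REMS-max" if t.wake_cut < r_RA < t.rem_cut else "wake-max"
        return "wake-active", subtype
    return "state-indifferent", "none"


def grade_strength(
    m_AW: float,
    m_NREM: float,
    m_REM: float,
    category: str,
    subtype: str,
    thresholds: ClassifierThresholds | None = None,
) -> tuple:
    """Strength grade from the fold change relative to the lower state mean.

    Effect size e = fold-change - 1: sleep-active nonREM subtypes use
    NREM/AW; REM-active uses min(REM/AW, REM/NREM); wake-max uses
    min(AW/NREM, AW/REM); wake/REMS-max uses AW/NREM (its REM activity is
    elevated by definition).  Grade bands: weak 0.25-0.5, moderate
    >0.5-1.0, strong >1.0.  Returns `(grade, flagged)`; e < 0.25 for a
    classified unit is flagged as a contract violation (grade "none").
    """
    t = (thresholds or ClassifierThresholds()).validate()
    if category in ("state-indifferent", "unclassifiable"):
        return "none", False
    if subtype == "REMS-active":
        e = min(m_REM / m_AW, m_REM / m_NREM) - 1.0
    elif category == "sleep-active":
        e = m_NREM / m_AW - 1.0
    elif subtype == "wake-max":
        e = min(m_AW / m_NREM, m_AW / m_REM) - 1.0
    else:  # wake/REMS-max
        e = m_AW / m_NREM - 1.0
    lo, hi = t.grade_weak
    if e < lo:
        return "none", True
    if e <= hi:
        return "weak", False
    if e <= t.grade_moderate[1]:
        return "moderate", False
    return "strong", False


def classify_units(
    profiles: pd.DataFrame,
    thresholds: ClassifierThresholds | None = None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every profiled unit; returns a calls table.

    Columns: unit_id (index), category, subtype, grade, flagged; animal_id
    and genotype are merged in when `metadata` is given.
    """
    t = (thresholds or ClassifierThresholds()).validate()
    records = []
    for uid, row in profiles.iterrows():
        category, subtype = classify_call(row["r_NA"], row["r_RA"], row["r_RN"], t)
        grade, flagged = grade_strength(
            row["m_AW"], row["m_NREM"], row["m_REM"], category, subtype, t
        )
        records.append((uid, category, subtype, grade, flagged))
    calls = pd.DataFrame(
        records, columns=["unit_id", "category", "subtype", "grade", "flagged"]
    ).set_index("unit_id")
    if metadata is not None:
        calls = calls.join(metadata.set_index("unit_id")[["animal_id", "genotype"]])
    return calls


# ---------------------------------------------------------------------------
# Census


def tabulate_census(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-animal, per-genotype counts of each subtype plus totals.

    `calls` must carry `animal_id` and `genotype` columns; state-indifferent
    units are counted under their own column, unclassifiable units are
    excluded.  An empty input yields an empty table.
    """
    cols = list(SUBTYPE_COLUMNS)
    if calls.empty:
        return pd.DataFrame(columns=["animal_id", "genotype", *cols, "total"])
    if not {"animal_id", "genotype"} <= set(calls.columns):
        raise ValueError("calls must carry animal_id and genotype")
    work = calls.copy()
    work["cell"] = np.where(
        work["category"] == "state-indifferent", "state-indifferent", work["subtype"]
    )
    work = work[work["category"] != "unclassifiable"]
    rows = []
    for (animal, geno), grp in work.groupby(["animal_id", "genotype"], sort=True):
        counts = {c: int((grp["cell"] == c).sum()) for c in cols}
        rows.append({"animal_id": animal, "genotype": geno, **counts, "total": len(grp)})
    return pd.DataFrame(rows, columns=["animal_id", "genotype", *cols, "total"])


def aggregate_census(census: pd.DataFrame, by: str = "genotype") -> pd.DataFrame:
    """Sum census counts over animals (default: one row per genotype)."""
    cols = [*SUBTYPE_COLUMNS, "total"]
    return census.groupby(by, sort=True)[cols].sum().reset_index()


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else np.nan


def census_percentages(counts) -> pd.DataFrame:
    """Category and subgroup percentages from subtype counts.

    `counts` maps each of the six subtype columns to an integer.  Returns a
    table of named fractions with exact numerator/denominator, the raw
    percentage, and the percentage rounded to the nearest integer (report
    parity).
    """
    c = {k: int(counts[k]) for k in SUBTYPE_COLUMNS}
    nonrem = c["nonREMS/REMS-max"] + c["nonREMS-max"]
    sleep = nonrem + c["REMS-active"]
    wake = c["wake-max"] + c["wake/REMS-max"]
    total = sleep + wake + c["state-indifferent"]
    rows = [
        ("sleep_active_of_total", sleep, total),
        ("wake_active_of_total", wake, total),
        ("state_indifferent_of_total", c["state-indifferent"], total),
        ("nonrem_sleep_active_of_sleep_active", nonrem, sleep),
        ("rems_active_of_sleep_active", c["REMS-active"], sleep),
        ("nonrem_rem_max_of_nonrem", c["nonREMS/REMS-max"], nonrem),
        ("nonrem_max_of_nonrem", c["nonREMS-max"], nonrem),
        ("wake_max_of_wake_active", c["wake-max"], wake),
        ("wake_rem_max_of_wake_active", c["wake/REMS-max"], wake),
    ]
    out = pd.DataFrame(rows, columns=["metric", "count", "denominator"])
    out["pct_raw"] = [_pct(n, d) for _, n, d in rows]
    out["pct"] = [
        int(np.floor(p + 0.5)) if np.isfinite(p) else -1 for p in out["pct_raw"]
    ]
    return out


# ---------------------------------------------------------------------------
# Logistic-regression validation


@dataclass
class LogisticValidationResult:
    """Maximum-likelihood logistic fit of a rule's class membership on its ratio(s)."""

    rule: str
    predictors: list
    coef: np.ndarray          # slope per predictor (intercept excluded)
    intercept: float
    se: np.ndarray
    pvalues: np.ndarray       # Wald, per predictor
    n: int
    separation: bool          # perfect separation -> coefficients unbounded


#: Predictor ratios of each threshold rule.
RULE_PREDICTORS = {
    "wake-active": ["r_NA"],
    "wake/REMS-max": ["r_NA", "r_RA"],
    "nonREM-sleep-active": ["r_NA"],
    "nonREMS/REMS-max": ["r_NA", "r_RN"],
    "REMS-active": ["r_RA", "r_RN"],
}


def logistic_validation(
    profiles: pd.DataFrame,
    outcome,
    rule: str,
    predictors: list | None = None,
) -> LogisticValidationResult:
    """Fit class membership ~ ratio(s) by maximum likelihood (statsmodels Logit).

    `outcome` is a boolean array aligned with `profiles`; predictors default
    to the rule's ratios (fitted jointly for two-ratio rules).  Perfect
    separation is detected and reported via the `separation` flag instead of
    pretending the unbounded coefficients converged.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    predictors = predictors or RULE_PREDICTORS[rule]
    X = profiles[predictors].to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; nothing to fit")

    Xc = sm.add_constant(X, has_constant="add")
    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        fitted = fit.predict(Xc)
        # Unbounded fits drift to huge slopes with saturated probabilities.
        separation = bool(
            np.any(np.abs(params[1:]) > 50)
            or np.all(np.abs(fitted - y) < 1e-8)
        )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        params = np.full(k + 1, np.nan)
        bse = np.full(k + 1, np.nan)
        pvals = np.full(k + 1, np.nan)
        separation = True
    return LogisticValidationResult(
        rule=rule,
        predictors=list(predictors),
        coef=np.asarray(params[1:]),
        intercept=float(params[0]),
        se=np.asarray(bse[1:]),
        pvalues=np.asarray(pvals[1:]),
        n=len(y),
        separation=separation,
    )
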