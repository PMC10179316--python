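#!/usr/bin/env python
"""Classify units into sleep-wake phenotypes; validate the rules and the census.

From the quality-filtered spontaneous epoch matrix: per-unit state-activity
profiles and ratio-threshold phenotype calls with strength grades; recovery
of the generator's assigned phenotypes; logistic-regression validation of
each threshold rule against ground-truth membership; the synthetic census;
and the category/subgroup percentages recomputed from the published
reference census counts.
"""

import json
from pathlib import Path

import pandas as pd

from vlpoca import (
    Hypnogram,
    census_percentages,
    classify_units,
    logistic_validation,
    state_activity_profiles,
    tabulate_census,
)
from vlpoca.config import CATEGORY_OF
from vlpoca.datasets import REFERENCE_SUBTYPE_COUNTS

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sess = RESULTS / "session_spontaneous"
    em = pd.read_csv(RESULTS / "epochs_spontaneous.csv", index_col="epoch_index")
    hyp = Hypnogram.read_csv(sess / "hypnogram.csv")
    meta = pd.read_csv(sess / "metadata.csv")
    truth = json.loads((sess / "ground_truth.json").read_text())

    profiles = state_activity_profiles(em, hyp)
    calls = classify_units(profiles, metadata=meta)
    profiles.to_csv(RESULTS / "profiles.csv")
    calls.to_csv(RESULTS / "calls.csv")

    got_sub = calls.apply(
        lambda r: "state-indifferent" if r["category"] == "state-indifferent" else r["subtype"],
        axis=1,
    )
    cat_ok = (calls["category"] == [CATEGORY_OF[truth[u]] for u in calls.index]).mean()
    sub_ok = (got_sub == [truth[u] for u in calls.index]).mean()
    print(f"recovered category for {100 * cat_ok:.0f}% and subtype for "
          f"{100 * sub_ok:.0f}% of {len(calls)} units")
    print(calls.groupby(["category", "subtype"]).size().to_string())

    census = tabulate_census(calls)
    census.to_csv(RESULTS / "census.tsv", sep="\t", index=False)

    # Logistic validation of each rule: ground-truth membership on the rule's ratios
    rows = []
    rule_truth = {
        "wake-active": lambda ph: CATEGORY_OF[ph] == "wake-active",
        "nonREM-sleep-active": lambda ph: ph in ("nonREMS/REMS-max", "nonREMS-max"),
        "REMS-active": lambda ph: ph == "REMS-active",
    }
    for rule, member_of in rule_truth.items():
        outcome = [member_of(truth[u]) for u in profiles.index]
        res = logistic_validation(profiles, outcome, rule)
        for pred, coef, p in zip(res.predictors, res.coef, res.pvalues):
            rows.append(
                {"rule": rule, "predictor": pred, "coef": coef, "pvalue": p,
                 "separation": res.separation, "n": res.n}
            )
    lr = pd.DataFrame(rows)
    lr.to_csv(RESULTS / "logistic_validation.tsv", sep="\t", index=False)
    print("\nlogistic validation (ground-truth membership ~ rule ratios):")
    print(lr.round(4).to_string(index=False))

    # Reference census percentages, recomputed from the published counts
    ref = pd.concat(
        [
            census_percentages(REFERENCE_SUBTYPE_COUNTS[g]).assign(genotype=g)
            for g in ("VGAT", "UNID")
        ]
    )
    ref.to_csv(RESULTS / "reference_census_percentages.tsv", sep="\t", index=False)
    print("\nreference census percentages (recomputed):")
    print(ref[["genotype", "metric", "count", "denominator", "pct"]].to_string(index=False))


if __name__ == "__main__":
    main()
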