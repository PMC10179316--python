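"""Reference inputs: the published VLPO census and group-mean activity vectors.

These are the printed per-animal phenotype counts and group-mean ΔF/F₀
vectors from the miniscope study of VLPO VGAT and unidentified (UNID)
neurons that this pipeline models.  They are inputs only — every percentage
or classification reported from them is recomputed by the package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_census",
    "REFERENCE_SUBTYPE_COUNTS",
    "REFERENCE_GROUP_MEANS",
]

# Per-animal counts: (animal, genotype, nonREM-sleep-active, REM-active,
# wake-max, wake/REMS-max, state-indifferent).  The published table merges
# the two nonREM subtypes into one column.
_CENSUS_ROWS = [
    ("VGAT#7", "VGAT", 7, 5, 7, 3, 1),
    ("VGAT#8", "VGAT", 11, 0, 8, 0, 2),
    ("VGAT#11", "VGAT", 21, 13, 32, 3, 2),
    ("VGAT#12", "VGAT", 15, 3, 6, 1, 1),
    ("VGAT#14", "VGAT", 21, 1, 22, 5, 3),
    ("VGAT#15", "VGAT", 13, 9, 29, 2, 6),
    ("VGAT#16", "VGAT", 32, 1, 12, 2, 4),
    ("#17", "UNID", 22, 8, 7, 2, 7),
    ("#1", "UNID", 5, 6, 13, 3, 2),
    ("#24", "UNID", 12, 5, 2, 10, 2),
]


def reference_census() -> pd.DataFrame:
    """Published per-animal census (nonREM subtypes merged, as printed)."""
    df = pd.DataFrame(
        _CENSUS_ROWS,
        columns=[
            "animal_id",
            "genotype",
            "nonREM-sleep-active",
            "REMS-active",
            "wake-max",
            "wake/REMS-max",
            "state-indifferent",
        ],
    )
    df["total"] = df.iloc[:, 2:].sum(axis=1)
    return df


#: Genotype-level subtype counts, including the nonREM subtype split that the
#: per-animal table does not break out (96/24 for VGAT, 33/6 for UNID).
REFERENCE_SUBTYPE_COUNTS = {
    "VGAT": {
        "nonREMS/REMS-max": 96,
        "nonREMS-max": 24,
        "REMS-active": 32,
        "wake-max": 116,
        "wake/REMS-max": 16,
        "state-indifferent": 19,
    },
    "UNID": {
        "nonREMS/REMS-max": 33,
        "nonREMS-max": 6,
        "REMS-active": 19,
        "wake-max": 22,
        "wake/REMS-max": 15,
        "state-indifferent": 11,
    },
}

#: Published group-mean ΔF/F₀ per state for the five VGAT subtypes, with the
#: subtype each vector belongs to (used as classifier worked examples).
REFERENCE_GROUP_MEANS = [
    {"subtype": "nonREMS/REMS-max", "AW": 1.04, "QW": 1.86, "NREM": 2.54, "REM": 2.76},
    {"subtype": "nonREMS-max", "AW": 0.87, "QW": 1.33, "NREM": 1.90, "REM": 0.61},
    {"subtype": "REMS-active", "AW": 0.60, "QW": 1.31, "NREM": 1.08, "REM": 3.47},
    {"subtype": "wake-max", "AW": 2.96, "QW": 1.75, "NREM": 0.82, "REM": 0.60},
    {"subtype": "wake/REMS-max", "AW": 2.62, "QW": 1.71, "NREM": 0.76, "REM": 2.50},
]
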