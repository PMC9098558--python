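"""Within-subject normalisation and cohort-level descriptive tables.

Overlap parameters (area OD, volume OD, EMD, centroid distance) vary widely
between individuals, so each value is normalised to the maximum the same
subject reached for the same parameter before averaging across the cohort.
The module emits tidy long-format tables — per-category subject fractions
and per-condition mean ± SD — suitable as direct input to any external
mixed-model or ANOVA machinery; no inference is performed here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "to_long_table",
    "normalize_within_subject",
    "od_category_distribution",
    "condition_summary",
]

PARAMETERS = ("area_od", "volume_od", "emd", "centroid_distance")

CATEGORY_ORDER = ("negligible", "low", "medium", "high", "very_high")


def to_long_table(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Reshape an overlap-report table into long parameter records.

    Input columns: subject, target, adjacent_set, intensity, kind, od_pct,
    category, emd_mm, centroid_dist_mm (one row per target x adjacent x
    kind).  Output: one row per subject x target x adjacent_set x intensity
    x parameter with a ``value`` column; OD rows keep their category label.
    """
    keys = ["subject", "target", "adjacent_set", "intensity"]
    rows = []
    for _, r in overlaps.iterrows():
        param = "area_od" if r["kind"] == "area" else "volume_od"
        rows.append(
            {**{k: r[k] for k in keys}, "parameter": param,
             "value": r["od_pct"], "category": r["category"]}
        )
        if r["kind"] == "area":  # topography metrics are kind-independent
            for param, col in (("emd", "emd_mm"), ("centroid_distance", "centroid_dist_mm")):
                rows.append(
                    {**{k: r[k] for k in keys}, "parameter": param,
                     "value": r[col], "category": ""}
                )
    return pd.DataFrame(rows)


def normalize_within_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each value by its subject x parameter maximum.

    Adds a ``normalized`` column; values land in (0, 1] with at least one
    exact 1 per subject x parameter group.  All-zero groups are left at 0
    with a warning; NaN values (e.g. undefined EMD) pass through as NaN.
    """
    table = table.copy()
    maxima = table.groupby(["subject", "parameter"])["value"].transform(
        lambda s: np.nanmax(s.to_numpy()) if s.notna().any() else np.nan
    )
    zero = maxima == 0
    if zero.any():
        groups = table.loc[zero, ["subject", "parameter"]].drop_duplicates()
        for _, g in groups.iterrows():
            warnings.warn(
                f"all-zero group subject={g['subject']} parameter={g['parameter']}; "
                "values left at 0",
                stacklevel=2,
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = table["value"] / maxima
    table["normalized"] = norm.where(~zero, 0.0)
    return table


def od_category_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of subjects per OD category for each overlap map condition.

    One row per target x adjacent_set x intensity x parameter (OD parameters
    only), with one column per category; each row sums to 1.
    """
    od = table[table["parameter"].isin(["area_od", "volume_od"])]
    od = od[od["category"] != ""]
    if od.empty:
        raise ValueError("no categorised OD records in table")
    counts = (
        od.groupby(["target", "adjacent_set", "intensity", "parameter"])["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for cat in CATEGORY_ORDER:
        if cat not in counts.columns:
            counts[cat] = 0.0
    return counts[list(CATEGORY_ORDER)].reset_index()


def condition_summary(table: pd.DataFrame, value_col: str = "normalized") -> pd.DataFrame:
    """Mean ± sample SD per parameter x target x adjacent_set x intensity.

    SD uses the n-1 estimator and is NaN (flagged undefined) for
    single-subject cells.  Both normalised and raw columns can be
    summarised via ``value_col``.
    """
    grouped = table.groupby(["parameter", "target", "adjacent_set", "intensity"])[
        value_col
    ]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sd_defined"] = out["n"] > 1
    return out
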