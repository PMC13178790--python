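"""Descriptive cohort reports: counts, column percentages, group tests.

Percentages follow the journal-table convention: 100 × count / denominator
rounded to the nearest integer with ties away from zero (22.52% prints as
23%). Group comparisons use chi-square for categorical blocks and
Kruskal–Wallis for continuous variables; with a single group the
percentages are still computed but p-values are suppressed with a note.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

RACE_ORDER = ("White", "Black", "Hispanic", "Other")


def round_percent(count: float, denom: float) -> int:
    """Nearest-integer percentage, ties away from zero."""
    if denom == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    x = 100.0 * count / denom
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _categorical_block(
    subjects: pd.DataFrame, col: str, categories, groups
) -> dict:
    out = {"variable": col, "levels": {}, "p_value": None, "note": ""}
    tab = pd.crosstab(subjects[col], subjects["race_ethnicity"])
    tab = tab.reindex(index=list(categories), columns=list(groups), fill_value=0)
    total = subjects[col].value_counts().reindex(list(categories), fill_value=0)
    for level in categories:
        row = {"total_n": int(total[level]),
               "total_pct": round_percent(total[level], len(subjects))}
        for g in groups:
            n_g = int((subjects["race_ethnicity"] == g).sum())
            row[g] = {"n": int(tab.loc[level, g]),
                      "pct": round_percent(tab.loc[level, g], n_g) if n_g else None}
        out["levels"][level] = row
    if len(groups) >= 2:
        observed = tab.loc[:, list(groups)].to_numpy()
        observed = observed[observed.sum(axis=1) > 0][:, observed.sum(axis=0) > 0]
        if observed.shape[0] >= 2 and observed.shape[1] >= 2:
            out["p_value"] = float(stats.chi2_contingency(observed)[1])
    else:
        out["note"] = "p-value suppressed: single group"
    return out


def _continuous_block(subjects: pd.DataFrame, col: str, groups) -> dict:
    out = {"variable": col, "median_iqr": {}, "p_value": None, "note": ""}
    x = subjects[col].dropna()
    out["median_iqr"]["Total"] = [float(np.percentile(x, q)) for q in (50, 25, 75)] if len(x) else None
    samples = []
    for g in groups:
        xg = subjects.loc[subjects["race_ethnicity"] == g, col].dropna()
        out["median_iqr"][g] = (
            [float(np.percentile(xg, q)) for q in (50, 25, 75)] if len(xg) else None
        )
        if len(xg):
            samples.append(xg.to_numpy())
    if len(samples) >= 2:
        out["p_value"] = float(stats.kruskal(*samples)[1])
    else:
        out["note"] = "p-value suppressed: single group"
    return out


def summarize_outcomes(subjects: pd.DataFrame) -> dict:
    """Transplant-access outcome table (waitlist status, KRT modality, donor
    type among transplant recipients), overall and by race."""
    if subjects.empty:
        raise ValueError("empty cohort")
    groups = [g for g in RACE_ORDER if g in set(subjects["race_ethnicity"])]
    report = {
        "n_total": len(subjects),
        "race_counts": {g: int((subjects["race_ethnicity"] == g).sum()) for g in groups},
        "race_pct": {g: round_percent((subjects["race_ethnicity"] == g).sum(), len(subjects))
                     for g in groups},
    }
    report["waitlisted"] = _categorical_block(
        subjects, "waitlist_status", ("not_waitlisted", "preemptive", "post_dialysis"), groups
    )
    report["krt_modality"] = _categorical_block(
        subjects, "krt_modality",
        ("in_center_hd", "home_hd", "pd", "preemptive_transplant"), groups,
    )
    tx = subjects[subjects["donor_type"].fillna("").astype(str) != ""]
    if len(tx):
        report["donor_type_among_transplants"] = _categorical_block(
            tx, "donor_type", ("living", "deceased", "unknown"), groups
        )
    return report


def summarize_characteristics(
    subjects: pd.DataFrame, visits: Optional[pd.DataFrame] = None
) -> dict:
    """Baseline characteristics by race: age at entry, sex, cause of CKD,
    number of creatinine measurements."""
    if subjects.empty:
        raise ValueError("empty cohort")
    groups = [g for g in RACE_ORDER if g in set(subjects["race_ethnicity"])]
    report = {
        "n_total": len(subjects),
        "race_pct": {g: round_percent((subjects["race_ethnicity"] == g).sum(), len(subjects))
                     for g in groups},
    }
    report["cause_of_ckd"] = _categorical_block(
        subjects, "ckd_cause", ("glomerular", "CAKUT", "other_unknown"), groups
    )
    if "sex" in subjects:
        report["sex"] = _categorical_block(subjects, "sex", ("female", "male"), groups)
    if "entry_age" in subjects:
        report["age_at_entry"] = _continuous_block(subjects, "entry_age", groups)
    if visits is not None:
        counts = visits.groupby("subject_id")["scr"].count().rename("n_creatinine")
        merged = subjects.merge(counts, left_on="subject_id", right_index=True, how="left")
        report["n_creatinine"] = _continuous_block(merged, "n_creatinine", groups)
    return report


def audit_percentages(report: dict) -> None:
    """Self-consistency: every printed percentage re-derives from its counts."""
    for block in report.values():
        if not isinstance(block, dict) or "levels" not in block:
            continue
        denom_by_group: dict = {}
        for level in block["levels"].values():
            for g, cell in level.items():
                if isinstance(cell, dict):
                    denom_by_group.setdefault(g, 0)
                    denom_by_group[g] += cell["n"]
        for level in block["levels"].values():
            for g, cell in level.items():
                if isinstance(cell, dict) and cell["pct"] is not None:
                    assert cell["pct"] == round_percent(cell["n"], denom_by_group[g])
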