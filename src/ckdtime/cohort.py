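"""Eligibility filtering and consort-style accounting.

The analysis cohort is youth with advanced, declining CKD observed before
kidney replacement therapy (KRT). A subject enters the analysis only if,
counting pre-KRT visits (strictly before the KRT date):

(a) at least 3 serum creatinine values;
(b) at least one bedside-Schwartz eGFR below 30 mL/min/1.73 m² — Schwartz is
    used for this criterion at every age and under every analysis scheme;
(c) a net eGFR decline (final pre-KRT value below the first);
(d) age under 25 years at cohort entry (follow-up past 25 is retained).

Each filter's exclusions are logged to a :class:`ConsortLog` whose
arithmetic is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import EquationConstants
from .egfr import egfr_bedside_schwartz

FILTER_ORDER = (
    "at_least_3_creatinines",
    "schwartz_egfr_below_30",
    "egfr_decline",
    "age_under_25_at_entry",
)


@dataclass
class ConsortStep:
    filter_name: str
    n_before: int
    n_excluded: int
    n_after: int


@dataclass
class ConsortLog:
    steps: list[ConsortStep] = field(default_factory=list)
    excluded_ids: dict[str, list] = field(default_factory=dict)

    def record(self, name: str, n_before: int, excluded: list) -> int:
        step = ConsortStep(name, n_before, len(excluded), n_before - len(excluded))
        self.steps.append(step)
        self.excluded_ids[name] = sorted(excluded)
        assert step.n_after == step.n_before - step.n_excluded
        return step.n_after

    def validate(self) -> None:
        for prev, cur in zip(self.steps, self.steps[1:]):
            assert cur.n_before == prev.n_after, "consort chain broken"
        for step in self.steps:
            assert step.n_after == step.n_before - step.n_excluded

    @property
    def n_final(self) -> int:
        return self.steps[-1].n_after if self.steps else 0

    def to_records(self) -> list[dict]:
        return [vars(s).copy() for s in self.steps]


def pre_krt_mask(visits: pd.DataFrame, subjects: pd.DataFrame) -> pd.Series:
    """True for visits strictly before the subject's KRT date (all visits when
    the subject never started KRT). KRT-day measurements are excluded."""
    krt = subjects.set_index("subject_id")["krt_date"]
    krt_for_visit = visits["subject_id"].map(krt)
    return krt_for_visit.isna() | (visits["visit_time"] < krt_for_visit)


def schwartz_eligibility_egfr(
    visits: pd.DataFrame, constants: EquationConstants | None = None
) -> pd.Series:
    """Bedside-Schwartz eGFR for every visit with a usable height (NaN otherwise)."""

    def one(row) -> float:
        h = row["height"]
        if pd.isna(h) or h <= 0:
            return float("nan")
        return egfr_bedside_schwartz(float(h), float(row["scr"]), constants)

    return visits.apply(one, axis=1)


def apply_eligibility(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    constants: EquationConstants | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ConsortLog]:
    """Apply filters (a)–(d) in order; return (visits, subjects, consort log).

    Subjects with zero visits are excluded (and logged) at filter (a), not
    treated as errors. Duplicate (subject, visit_time) rows are a validation
    error — they indicate a malformed extract, not a clinical reality.
    """
    dupes = visits.duplicated(subset=["subject_id", "visit_time"])
    if dupes.any():
        bad = visits.loc[dupes, ["subject_id", "visit_time"]].iloc[0]
        raise ValueError(
            f"duplicate (subject_id, visit_time) rows, e.g. {tuple(bad)}"
        )
    visits = visits.sort_values(["subject_id", "visit_time"], kind="mergesort")

    log = ConsortLog()
    ids = list(subjects["subject_id"])

    pre = visits[pre_krt_mask(visits, subjects)].copy()
    pre["_elig_egfr"] = schwartz_eligibility_egfr(pre, constants)
    n_scr = pre.groupby("subject_id")["scr"].count()

    # (a) >= 3 pre-KRT serum creatinine values
    keep = [i for i in ids if n_scr.get(i, 0) >= 3]
    log.record(FILTER_ORDER[0], len(ids), [i for i in ids if i not in set(keep)])
    ids = keep

    # (b) >= 1 bedside-Schwartz eGFR < 30 pre-KRT
    has_low = pre.groupby("subject_id")["_elig_egfr"].min() < 30.0
    keep = [i for i in ids if bool(has_low.get(i, False))]
    log.record(FILTER_ORDER[1], len(ids), [i for i in ids if i not in set(keep)])
    ids = keep

    # (c) final pre-KRT eGFR below the first
    first = pre.dropna(subset=["_elig_egfr"]).groupby("subject_id")["_elig_egfr"].first()
    last = pre.dropna(subset=["_elig_egfr"]).groupby("subject_id")["_elig_egfr"].last()
    keep = [i for i in ids if i in first.index and last[i] < first[i]]
    log.record(FILTER_ORDER[2], len(ids), [i for i in ids if i not in set(keep)])
    ids = keep

    # (d) age < 25 at cohort entry
    entry_age = visits.groupby("subject_id")["age"].first()
    keep = [i for i in ids if float(entry_age.get(i, float("inf"))) < 25.0]
    log.record(FILTER_ORDER[3], len(ids), [i for i in ids if i not in set(keep)])
    ids = keep

    log.validate()
    kept = set(ids)
    out_subjects = subjects[subjects["subject_id"].isin(kept)].reset_index(drop=True)
    out_visits = visits[visits["subject_id"].isin(kept)].reset_index(drop=True)
    return out_visits, out_subjects, log
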