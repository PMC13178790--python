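"""Threshold-crossing times and time spent with low eGFR.

Each subject's fitted trajectory a + b t + c t² is inverted analytically to
find downward crossings of the clinically meaningful thresholds: 30
mL/min/1.73 m² (when transplant preparation typically begins) and 10 (the
median eGFR at dialysis start). The primary exposure is the model-predicted
time between the two, in months; a sensitivity variant anchors the interval
end at the observed KRT start date instead of the modelled crossing of 10.

Race contrasts in those durations are estimated by ordinary least squares
on subject-level durations with White as the reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
import statsmodels.formula.api as smf

from .trajectory import TrajectoryFit

DEFAULT_HORIZON_YEARS = 30.0
RACE_GROUPS = ("White", "Black", "Hispanic", "Other")


@dataclass
class CrossingSummary:
    subject_id: str
    t30: Optional[float]  # years at first downward crossing of 30
    t10: Optional[float]  # years at first downward crossing of 10
    low_egfr_months: Optional[float]  # 12 * (t10 - t30)
    months_30_to_krt: Optional[float]  # 12 * (krt_date - t30)
    months_t10_to_krt: Optional[float]  # 12 * (krt_date - t10); negative when
    # the modelled crossing of 10 falls after the observed KRT start
    crossing_status: str  # both | only30 | none


@dataclass
class EffectEstimate:
    contrast_label: str
    beta_months: float
    ci_low: float
    ci_high: float
    p_value: float
    scheme: str = ""
    outcome_field: str = "low_egfr_months"
    estimation_method: str = "ols"

    def to_dict(self) -> dict:
        return vars(self).copy()


def crossing_time(
    coeffs: tuple[float, float, float],
    threshold: float,
    horizon: float = DEFAULT_HORIZON_YEARS,
    t_min: float = 0.0,
) -> Optional[float]:
    """Earliest downward crossing of ``threshold`` by a + b t + c t².

    Returns the smallest root t in [t_min, horizon] at which the curve equals
    the threshold with strictly negative local slope, or ``None`` when no
    such root exists (flat or upward-moving trajectories, vertex above the
    threshold, crossing beyond the horizon).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    a, b, c = (float(v) for v in coeffs)
    d = a - threshold
    roots: list[float] = []
    if abs(c) < 1e-12:
        if abs(b) >= 1e-12:
            roots = [-d / b]
    else:
        disc = b * b - 4.0 * c * d
        if disc >= 0:
            s = math.sqrt(disc)
            roots = [(-b - s) / (2.0 * c), (-b + s) / (2.0 * c)]
    down = [t for t in sorted(roots)
            if t_min <= t <= horizon and (b + 2.0 * c * t) < 0.0]
    return down[0] if down else None


def low_egfr_duration(
    fit: TrajectoryFit,
    subject_id: str,
    krt_date: Optional[float] = None,
    upper_threshold: float = 30.0,
    lower_threshold: float = 10.0,
    horizon: float = DEFAULT_HORIZON_YEARS,
) -> CrossingSummary:
    """Crossing times and low-eGFR months for one fitted subject.

    t30 is searched from -horizon: a subject may enter observation already
    below 30, in which case the modelled crossing predates their first visit
    and t30 is negative on their clock. Durations are differences, so they
    are invariant to where that clock starts.
    """
    coeffs = fit.subject_coeffs(subject_id)
    t30 = crossing_time(coeffs, upper_threshold, horizon=horizon, t_min=-horizon)
    t10 = crossing_time(coeffs, lower_threshold, horizon=horizon, t_min=-horizon)
    if t30 is not None and t10 is not None:
        status = "both"
        months = 12.0 * (t10 - t30)
    elif t30 is not None:
        status, months = "only30", None
    else:
        status, months = "none", None
    return CrossingSummary(
        subject_id=subject_id,
        t30=t30,
        t10=t10,
        low_egfr_months=months,
        months_30_to_krt=(
            12.0 * (krt_date - t30) if (krt_date is not None and t30 is not None) else None
        ),
        months_t10_to_krt=(
            12.0 * (krt_date - t10) if (krt_date is not None and t10 is not None) else None
        ),
        crossing_status=status,
    )


def derive_crossing_summaries(
    fit: TrajectoryFit, subjects: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Per-subject :func:`low_egfr_duration` for everyone in the fit, as a table."""
    krt = subjects.set_index("subject_id")["krt_date"] if "krt_date" in subjects else None
    rows = []
    for sid in fit.random_effects:
        kd = None
        if krt is not None and sid in krt.index and pd.notna(krt[sid]):
            kd = float(krt[sid])
        rows.append(vars(low_egfr_duration(fit, sid, krt_date=kd, **kwargs)))
    return pd.DataFrame(rows)


def race_effect_regression(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    outcome_field: str = "low_egfr_months",
    scheme: str = "",
    reference: str = "White",
) -> list[EffectEstimate]:
    """OLS of a months field on race indicators; White is the reference.

    Subjects whose trajectory never crosses both thresholds carry a missing
    duration and drop out of the regression (their count is visible in the
    summaries table's ``crossing_status``).
    """
    df = summaries.merge(
        profiles[["subject_id", "race_ethnicity"]], on="subject_id"
    ).dropna(subset=[outcome_field])
    races = set(df["race_ethnicity"])
    if reference not in races:
        raise ValueError(f"reference group {reference!r} is empty")
    if len(races) < 2:
        raise ValueError("need >= 2 race groups for contrasts")
    res = smf.ols(
        f"{outcome_field} ~ C(race_ethnicity, Treatment({reference!r}))", df
    ).fit()
    out = []
    conf = res.conf_int(alpha=0.05)
    for name in res.params.index:
        if name == "Intercept":
            continue
        group = name.split("[T.")[1].rstrip("]")
        out.append(
            EffectEstimate(
                contrast_label=f"{group} vs {reference}",
                beta_months=float(res.params[name]),
                ci_low=float(conf.loc[name, 0]),
                ci_high=float(conf.loc[name, 1]),
                p_value=float(res.pvalues[name]),
                scheme=scheme,
                outcome_field=outcome_field,
                estimation_method="ols",
            )
        )
    return out
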