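"""Creatinine-based eGFR estimation and age dispatch.

Two equation *schemes* are supported, mirroring how eGFR is produced in
pediatric nephrology practice versus the harmonized research alternative:

``schwartz_ckdepi``
    bedside Schwartz (k × height_cm / SCr) while the patient is < 18 years,
    switching to the race-free CKD-EPI 2021 creatinine equation at the 18th
    birthday (a deliberate step discontinuity mid-follow-up).
``u25``
    the CKiD U25 creatinine equation — a piecewise age- and sex-specific
    multiplier times height_m / SCr — applied at every age in [1, 25).

All outputs are in mL/min/1.73 m². Heights are carried in cm on
:class:`VisitRecord` and converted internally where an equation wants metres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import pandas as pd

from .constants import EquationConstants, load_constants

logger = logging.getLogger(__name__)

Scheme = Literal["schwartz_ckdepi", "u25"]
SCHEMES: tuple[Scheme, ...] = ("schwartz_ckdepi", "u25")

HEIGHT_PLAUSIBLE_CM = (40.0, 220.0)


class InvalidInputError(ValueError):
    """A physiologically impossible input (named field) was supplied."""


class DispatchViolationError(ValueError):
    """An equation was called outside the age range it is dispatched for."""


@dataclass(frozen=True)
class VisitRecord:
    """One clinic/study observation on a subject's own clock."""

    subject_id: str
    age: float  # decimal years
    scr: float  # serum creatinine, mg/dL
    visit_time: float  # years since the subject's first record
    height: Optional[float] = None  # cm

    def __post_init__(self) -> None:
        if self.scr <= 0:
            raise InvalidInputError(f"scr must be > 0, got {self.scr}")
        if self.age < 0:
            raise InvalidInputError(f"age must be >= 0, got {self.age}")
        if self.visit_time < 0:
            raise InvalidInputError(f"visit_time must be >= 0, got {self.visit_time}")


def egfr_bedside_schwartz(
    height_cm: float, scr: float, constants: EquationConstants | None = None
) -> float:
    """Bedside Schwartz eGFR: k × height(cm) / SCr."""
    c = constants or _default_constants()
    if height_cm is None or not height_cm > 0:
        raise InvalidInputError(f"height must be > 0, got {height_cm}")
    if not scr > 0:
        raise InvalidInputError(f"scr must be > 0, got {scr}")
    _warn_height(height_cm)
    return c.schwartz_k * height_cm / scr


def egfr_ckdepi2021(
    scr: float, age: float, sex: str, constants: EquationConstants | None = None
) -> float:
    """CKD-EPI 2021 creatinine eGFR (race-free, adults only in this pipeline)."""
    c = constants or _default_constants()
    if age < 18:
        raise DispatchViolationError(
            f"CKD-EPI 2021 is dispatched only at age >= 18 here, got age={age}"
        )
    if not scr > 0:
        raise InvalidInputError(f"scr must be > 0, got {scr}")
    kappa = c.ckdepi_kappa_by_sex[sex]
    alpha = c.ckdepi_alpha_by_sex[sex]
    ratio = scr / kappa
    value = (
        c.ckdepi_scale
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** c.ckdepi_exponent_high
        * c.ckdepi_age_factor**age
    )
    if sex == "female":
        value *= c.ckdepi_female_factor
    return value


def egfr_u25(
    height_m: float,
    scr: float,
    age: float,
    sex: str,
    constants: EquationConstants | None = None,
) -> float:
    """CKiD U25 creatinine eGFR: k(age, sex) × height(m) / SCr."""
    c = constants or _default_constants()
    if not 1 <= age < 25:
        raise DispatchViolationError(f"U25 applies to ages [1, 25), got age={age}")
    if height_m is None or not height_m > 0:
        raise InvalidInputError(f"height must be > 0, got {height_m}")
    if not scr > 0:
        raise InvalidInputError(f"scr must be > 0, got {scr}")
    _warn_height(height_m * 100.0)
    return c.u25_k(age, sex) * height_m / scr


def invert_scheme_scr(
    egfr: float,
    age: float,
    sex: str,
    height_cm: float,
    scheme: Scheme = "schwartz_ckdepi",
    constants: EquationConstants | None = None,
) -> float:
    """Serum creatinine that would yield ``egfr`` under the scheme's equation.

    Closed-form inverse; used by the synthetic generator so creatinine (the
    actual observable) is what gets simulated and the equation layer is
    genuinely exercised on the way back.
    """
    c = constants or _default_constants()
    if egfr <= 0:
        raise InvalidInputError(f"egfr must be > 0, got {egfr}")
    if scheme == "u25":
        return c.u25_k(age, sex) * (height_cm / 100.0) / egfr
    if age < 18:
        return c.schwartz_k * height_cm / egfr
    kappa = c.ckdepi_kappa_by_sex[sex]
    alpha = c.ckdepi_alpha_by_sex[sex]
    base = c.ckdepi_scale * c.ckdepi_age_factor**age
    if sex == "female":
        base *= c.ckdepi_female_factor
    at_kappa = base  # both piecewise factors equal 1 at scr == kappa
    if egfr >= at_kappa:  # low-creatinine branch
        return kappa * (egfr / base) ** (1.0 / alpha)
    return kappa * (egfr / base) ** (1.0 / c.ckdepi_exponent_high)


def egfr_dispatch(
    visit: VisitRecord,
    sex: str,
    scheme: Scheme,
    constants: EquationConstants | None = None,
) -> float:
    """Route one visit to the scheme's equation for the visit's decimal age."""
    c = constants or _default_constants()
    if scheme == "schwartz_ckdepi":
        if visit.age < 18:
            if visit.height is None:
                raise InvalidInputError("height missing for bedside Schwartz")
            return egfr_bedside_schwartz(visit.height, visit.scr, c)
        return egfr_ckdepi2021(visit.scr, visit.age, sex, c)
    if scheme == "u25":
        if visit.height is None:
            raise InvalidInputError("height missing for U25")
        return egfr_u25(visit.height / 100.0, visit.scr, visit.age, sex, c)
    raise ValueError(f"unknown scheme {scheme!r}")


def compute_egfr_table(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    scheme: Scheme,
    constants: EquationConstants | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Add an ``egfr`` column to a long visit table under one scheme.

    Visits the scheme cannot evaluate (missing height for a height-based
    equation, age outside the U25 range) are skipped, not fatal: each skip is
    recorded and returned so callers can reconcile
    ``n_visits == n_values + n_skipped``.
    """
    c = constants or _default_constants()
    sex_by_id = subjects.set_index("subject_id")["sex"]
    out_rows, skipped = [], []
    for row in visits.itertuples(index=False):
        height = getattr(row, "height", None)
        if height is not None and (pd.isna(height) or height <= 0):
            height = None
        try:
            visit = VisitRecord(
                subject_id=row.subject_id,
                age=float(row.age),
                scr=float(row.scr),
                visit_time=float(row.visit_time),
                height=None if height is None else float(height),
            )
            value = egfr_dispatch(visit, sex_by_id[row.subject_id], scheme, c)
        except (InvalidInputError, DispatchViolationError) as exc:
            skipped.append(
                {"subject_id": row.subject_id, "visit_time": row.visit_time,
                 "reason": str(exc)}
            )
            logger.info("skipping visit %s@%s: %s", row.subject_id, row.visit_time, exc)
            continue
        rec = row._asdict()
        rec["egfr"] = value
        out_rows.append(rec)
    out = pd.DataFrame(out_rows, columns=[*visits.columns, "egfr"])
    assert len(visits) == len(out) + len(skipped)
    return out, skipped


_CONSTANTS_CACHE: EquationConstants | None = None


def _default_constants() -> EquationConstants:
    global _CONSTANTS_CACHE
    if _CONSTANTS_CACHE is None:
        _CONSTANTS_CACHE = load_constants()
    return _CONSTANTS_CACHE


def _warn_height(height_cm: float) -> None:
    lo, hi = HEIGHT_PLAUSIBLE_CM
    if not lo <= height_cm <= hi:
        logger.warning("height %.1f cm outside plausible range [%g, %g]", height_cm, lo, hi)
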