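"""Urine protein-measure harmonization.

Clinical records mix three proteinuria measures: quantitative urine
albumin/creatinine ratios (ACR, mg/g), protein/creatinine ratios (PCR,
mg/g), and semi-quantitative dipstick categories. Outcome models want one
covariate on one scale; this module converts everything to ACR and picks the
value anchored to a model's time origin — the most recent measure at or
before the origin when one exists, otherwise the nearest measure in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

from .constants import DIPSTICK_CATEGORIES, ConversionModel, load_conversion_model

MISSING = None  # sentinel: no urine measure available


@dataclass(frozen=True)
class UrineMeasure:
    kind: Literal["pcr", "acr", "dipstick"]
    value: Union[float, str]  # mg/g for pcr/acr; ordinal category for dipstick
    measured_time: float  # years on the subject clock

    def __post_init__(self) -> None:
        if self.kind == "dipstick":
            if self.value not in DIPSTICK_CATEGORIES:
                raise ValueError(
                    f"unknown dipstick category {self.value!r}; "
                    f"accepted: {', '.join(DIPSTICK_CATEGORIES)}"
                )
        elif float(self.value) < 0:
            raise ValueError(f"{self.kind} value must be >= 0, got {self.value}")


def dipstick_to_acr(category: str, model: ConversionModel | None = None) -> float:
    """Map an ordinal dipstick category to an ACR (mg/g) via the loaded table."""
    m = model or _default_model()
    if category not in DIPSTICK_CATEGORIES:
        raise ValueError(
            f"unknown dipstick category {category!r}; "
            f"accepted: {', '.join(DIPSTICK_CATEGORIES)}"
        )
    return m.dipstick_to_acr_map[category]


def acr_to_pcr(acr: float, age: float, model: ConversionModel | None = None) -> float:
    """Convert ACR to PCR with the age group's log-linear coefficients."""
    m = model or _default_model()
    if acr < 0:
        raise ValueError(f"acr must be >= 0, got {acr}")
    g = m.group_for_age(age)
    if acr == 0:
        return 0.0
    return math.exp(g.log_intercept) * acr**g.log_slope


def pcr_to_acr(pcr: float, age: float, model: ConversionModel | None = None) -> float:
    """Inverse of :func:`acr_to_pcr` (the log-linear form is invertible)."""
    m = model or _default_model()
    if pcr < 0:
        raise ValueError(f"pcr must be >= 0, got {pcr}")
    g = m.group_for_age(age)
    if pcr == 0:
        return 0.0
    return (pcr / math.exp(g.log_intercept)) ** (1.0 / g.log_slope)


def harmonize_to_acr(
    measure: UrineMeasure, age: float, model: ConversionModel | None = None
) -> float:
    if measure.kind == "acr":
        return float(measure.value)
    if measure.kind == "dipstick":
        return dipstick_to_acr(str(measure.value), model)
    return pcr_to_acr(float(measure.value), age, model)


def select_albuminuria(
    measures: Sequence[UrineMeasure],
    t_origin: float,
    age_at_origin: float = 10.0,
    model: ConversionModel | None = None,
) -> Optional[float]:
    """Pick the ACR covariate value anchored at ``t_origin``.

    Preference order: the measure with the largest ``measured_time`` at or
    before the origin; failing that, the measure minimizing
    ``|measured_time - t_origin|`` with ties broken toward the earlier
    (pre-origin) measure and then input order. Dipstick and PCR records are
    converted to ACR before selection. Returns ``None`` when the list is
    empty — a valid "missing" flag, not an error.
    """
    if not math.isfinite(t_origin):
        raise ValueError("t_origin must be finite")
    if not measures:
        return MISSING
    indexed = list(enumerate(measures))
    prior = [(m.measured_time, i) for i, m in indexed if m.measured_time <= t_origin]
    if prior:
        # latest prior; tie at the same time -> first in input order
        best_time = max(t for t, _ in prior)
        idx = min(i for t, i in prior if t == best_time)
    else:
        keyed = sorted(
            indexed, key=lambda p: (abs(p[1].measured_time - t_origin),
                                    p[1].measured_time, p[0])
        )
        idx = keyed[0][0]
    chosen = measures[idx]
    return harmonize_to_acr(chosen, age_at_origin, model)


def log_albuminuria(acr: Optional[float]) -> Optional[float]:
    """Covariate transform for outcome models: log(ACR + 1), admitting zeros."""
    if acr is None:
        return None
    return math.log(acr + 1.0)


_MODEL_CACHE: ConversionModel | None = None


def _default_model() -> ConversionModel:
    global _MODEL_CACHE
    if _MODEL_CACHE is None:
        _MODEL_CACHE = load_conversion_model()
    return _MODEL_CACHE
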