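"""Equation constants and biomarker-conversion models.

All numeric constants live in a versioned YAML file
(``ckdtime/data/equations.yaml``) rather than in code, so a transcription
correction or a new set of validated conversion coefficients never touches
the implementation. :func:`load_constants` and :func:`load_conversion_model`
read the packaged defaults or any user-supplied file with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

DIPSTICK_CATEGORIES = ("negative", "trace", "1+", "2+", "3+", "4+")


@dataclass(frozen=True)
class U25Band:
    """One (sex, age-band) piece of the CKiD U25 multiplier table.

    k(age) = ``k_base * per_year_factor ** (age - ref_age)`` evaluated at the
    exact decimal age; bands partition [1, 25) per sex with no overlap.
    """

    sex: str
    age_lo: float
    age_hi: float
    k_base: float
    per_year_factor: float
    ref_age: float

    def k(self, age: float) -> float:
        return self.k_base * self.per_year_factor ** (age - self.ref_age)


@dataclass(frozen=True)
class EquationConstants:
    schwartz_k: float
    ckdepi_scale: float
    ckdepi_kappa_by_sex: Mapping[str, float]
    ckdepi_alpha_by_sex: Mapping[str, float]
    ckdepi_exponent_high: float
    ckdepi_age_factor: float
    ckdepi_female_factor: float
    u25_bands: Sequence[U25Band] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        positives = [
            self.schwartz_k,
            self.ckdepi_scale,
            self.ckdepi_age_factor,
            self.ckdepi_female_factor,
            *self.ckdepi_kappa_by_sex.values(),
        ]
        if any(v <= 0 for v in positives):
            raise ValueError("equation constants must be strictly positive")
        for sex in ("female", "male"):
            bands = sorted(
                (b for b in self.u25_bands if b.sex == sex), key=lambda b: b.age_lo
            )
            if not bands:
                raise ValueError(f"u25 table has no bands for sex={sex!r}")
            if bands[0].age_lo != 1.0 or bands[-1].age_hi != 25.0:
                raise ValueError("u25 bands must span ages [1, 25)")
            for lo, hi in zip(bands[1:], bands[:-1]):
                if lo.age_lo != hi.age_hi:
                    raise ValueError("u25 bands must partition [1, 25) without gaps")
            if any(b.k_base <= 0 or b.per_year_factor <= 0 for b in bands):
                raise ValueError("u25 multipliers must be strictly positive")

    def u25_k(self, age: float, sex: str) -> float:
        for band in self.u25_bands:
            if band.sex == sex and band.age_lo <= age < band.age_hi:
                return band.k(age)
        raise LookupError(f"no U25 band for age={age}, sex={sex!r}")


@dataclass(frozen=True)
class AcrPcrGroup:
    """Age-group coefficients for ACR→PCR: PCR = exp(b0) * ACR**b1."""

    age_lo: float
    age_hi: float
    log_intercept: float
    log_slope: float


@dataclass(frozen=True)
class ConversionModel:
    """Dipstick→ACR ordinal map plus age-grouped ACR→PCR coefficients."""

    dipstick_to_acr_map: Mapping[str, float]
    acr_pcr_groups: Sequence[AcrPcrGroup]

    def __post_init__(self) -> None:
        missing = [c for c in DIPSTICK_CATEGORIES if c not in self.dipstick_to_acr_map]
        if missing:
            raise ValueError(f"dipstick map missing categories: {missing}")
        values = [self.dipstick_to_acr_map[c] for c in DIPSTICK_CATEGORIES]
        if any(v < 0 for v in values):
            raise ValueError("dipstick map values must be nonnegative")
        if any(b > a for b, a in zip(values, values[1:])):
            raise ValueError("dipstick map must be monotone nondecreasing")
        if any(g.log_slope <= 0 for g in self.acr_pcr_groups):
            raise ValueError("acr->pcr slope must be positive (monotone conversion)")

    def group_for_age(self, age: float) -> AcrPcrGroup:
        for g in self.acr_pcr_groups:
            if g.age_lo <= age < g.age_hi:
                return g
        raise LookupError(f"age {age} outside configured ACR/PCR age groups")


def _read_yaml(path: str | Path | None) -> dict:
    if path is None:
        ref = resources.files("ckdtime.data") / "equations.yaml"
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())


def load_constants(path: str | Path | None = None) -> EquationConstants:
    """Load :class:`EquationConstants` from YAML (packaged defaults if None)."""
    raw = _read_yaml(path)
    ck = raw["ckdepi2021"]
    return EquationConstants(
        schwartz_k=float(raw["schwartz"]["k"]),
        ckdepi_scale=float(ck["scale"]),
        ckdepi_kappa_by_sex={k: float(v) for k, v in ck["kappa"].items()},
        ckdepi_alpha_by_sex={k: float(v) for k, v in ck["alpha"].items()},
        ckdepi_exponent_high=float(ck["exponent_high"]),
        ckdepi_age_factor=float(ck["age_factor"]),
        ckdepi_female_factor=float(ck["female_factor"]),
        u25_bands=tuple(U25Band(**band) for band in raw["u25"]),
    )


def load_conversion_model(path: str | Path | None = None) -> ConversionModel:
    """Load :class:`ConversionModel` from YAML (packaged defaults if None)."""
    raw = _read_yaml(path)
    return ConversionModel(
        dipstick_to_acr_map={str(k): float(v) for k, v in raw["dipstick_to_acr"].items()},
        acr_pcr_groups=tuple(AcrPcrGroup(**g) for g in raw["acr_pcr"]),
    )
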