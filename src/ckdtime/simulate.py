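"""Synthetic longitudinal cohorts with known ground truth.

The restricted study data cannot be shared, so every pipeline stage is
exercised on simulated cohorts that carry the statistical structure the
analysis assumes: per-subject declining eGFR trajectories with mild
curvature, race-differential progression, roughly 6-monthly visits,
multiplicative creatinine measurement noise, KRT onset near eGFR 10,
transplant-access outcomes drawn from logistic models in the *true* months
spent with eGFR 10–30, and partially missing urine measures including
dipstick-only records.

Creatinine — not eGFR — is the generated observable: true eGFR is pushed
through the inverse of the clinical-practice equations (Schwartz < 18,
CKD-EPI 2021 ≥ 18) so the equation layer, including the 18th-birthday
dispatch switch, is genuinely exercised on the way back.

Race-differential progression is parametrized directly in duration space:
each subject's true months from eGFR 30 to 10 is drawn from a shifted gamma
whose mean is the configured race-specific value, and the trajectory is
built on a clock anchored at the 30-crossing so that drawn duration is the
exact ground truth. The configured between-race mean duration difference is
therefore exactly the estimand the downstream regression targets.
Observation windows emulate the study's collection design: creatinines
roughly every 6 months over the ~3 years preceding KRT onset, so every
regular subject satisfies the eligibility filters and only the deliberately
injected violators fail them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .constants import DIPSTICK_CATEGORIES
from .egfr import invert_scheme_scr

RACES = ("White", "Black", "Hispanic", "Other")
CAUSES = ("glomerular", "CAKUT", "other_unknown")

# Table-style cohort margins used as generator defaults (race shares, sex,
# cause mix by race) so synthetic cohorts resemble the study population.
_RACE_PROBS = {"White": 160 / 333, "Black": 72 / 333, "Hispanic": 65 / 333, "Other": 36 / 333}
_CAUSE_PROBS = {
    "White": (23 / 160, 51 / 160, 86 / 160),
    "Black": (23 / 72, 18 / 72, 31 / 72),
    "Hispanic": (18 / 65, 15 / 65, 32 / 65),
    "Other": (11 / 36, 5 / 36, 20 / 36),
}


@dataclass
class GeneratorConfig:
    n_subjects: int = 333
    race_probs: Mapping[str, float] = field(default_factory=lambda: dict(_RACE_PROBS))
    female_prob: float = 115 / 333
    cause_probs_by_race: Mapping[str, tuple] = field(default_factory=lambda: dict(_CAUSE_PROBS))
    entry_age_range: tuple[float, float] = (3.0, 19.0)
    # observation window: creatinine collection spans ~this many years before
    # KRT onset (uniform jitter of +/- lead_in_jitter), per the emulated
    # study's supplemental-collection design
    lead_in_years: float = 3.0
    lead_in_jitter: float = 0.5
    # true months from eGFR 30 to 10, shifted-gamma(shift 6 months) per race
    duration_mean_months_by_race: Mapping[str, float] = field(
        default_factory=lambda: {"White": 30.0, "Black": 24.0, "Hispanic": 29.0, "Other": 28.0}
    )
    duration_sd_months: float = 10.0
    duration_shift_months: float = 6.0
    curvature_mean: float = 0.3  # eGFR / yr^2
    curvature_sd: float = 0.05
    visit_interval: float = 0.5  # years
    visit_jitter_sd: float = 0.05
    scr_noise_cv: float = 0.05
    krt_threshold_egfr: float = 10.0
    krt_threshold_offset_by_race: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in RACES}
    )
    # outcome -> (logit intercept, log-OR per true year with low eGFR)
    outcome_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "preemptive_transplant": (-1.094, math.log(1.45)),
            "living_donor_transplant": (-1.853, math.log(1.42)),
            "preemptive_waitlisting": (1.208, 0.0),
        }
    )
    # log-ACR (mg/g) mean/sd by CKD cause
    albuminuria_by_cause: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "glomerular": (6.2, 1.5),
            "CAKUT": (2.7, 1.8),
            "other_unknown": (3.2, 1.8),
        }
    )
    urine_missing_prob: float = 0.15
    urine_kind_probs: Mapping[str, float] = field(
        default_factory=lambda: {"acr": 0.5, "pcr": 0.25, "dipstick": 0.25}
    )
    # fraction of subjects deliberately violating each eligibility filter
    violator_fracs: Mapping[str, float] = field(
        default_factory=lambda: {"few_visits": 0.05, "no_low_egfr": 0.05, "non_decline": 0.05}
    )

    def __post_init__(self) -> None:
        for name, probs in [("race_probs", self.race_probs.values()),
                            ("urine_kind_probs", self.urine_kind_probs.values())]:
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        for r, p in self.cause_probs_by_race.items():
            if abs(sum(p) - 1.0) > 1e-6:
                raise ValueError(f"cause probs for {r} must sum to 1")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be > 0")
        if any(m <= self.duration_shift_months for m in self.duration_mean_months_by_race.values()):
            raise ValueError(
                "mean durations must exceed the gamma shift (non-declining "
                "mean trajectory implied otherwise)"
            )

    @property
    def slope_mean_by_race(self) -> dict[str, float]:
        """Implied mean linear decline rate (eGFR/yr, negative) per race."""
        return {
            r: -20.0 / (m / 12.0) for r, m in self.duration_mean_months_by_race.items()
        }


_DIPSTICK_EDGES = [25.0, 95.0, 300.0, 700.0, 1400.0]  # bin true ACR -> category


def _acr_to_dipstick(acr: float) -> str:
    idx = sum(acr >= e for e in _DIPSTICK_EDGES)
    return DIPSTICK_CATEGORIES[idx]


def _height_cm(age: float, sex: str) -> float:
    """Piecewise-linear height-for-age with a sex offset after age 12.

    Deliberately simple and non-anthropometric: it only needs to provide a
    plausible, smooth, strictly positive height so the height-based
    equations have realistic inputs.
    """
    if age <= 1.0:
        h = 50.0 + 25.0 * age
    elif age <= 12.0:
        h = 75.0 + 6.0 * (age - 1.0)
    elif age <= 17.0:
        rate = 5.5 if sex == "male" else 4.0
        h = 141.0 + rate * (age - 12.0)
    else:
        h = 141.0 + (27.5 if sex == "male" else 20.0)
    return min(h, 200.0)


def _downward_root(a: float, b: float, c: float, threshold: float) -> Optional[float]:
    d = a - threshold
    if abs(c) < 1e-9:
        return -d / b if b < 0 else None
    disc = b * b - 4.0 * c * d
    if disc < 0:
        return None
    s = math.sqrt(disc)
    roots = sorted([(-b - s) / (2 * c), (-b + s) / (2 * c)])
    for t in roots:
        if b + 2 * c * t < 0:
            return t
    return None


def generate_cohort(
    config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (visits, subjects, ground_truth) tables.

    Deterministic for fixed (config, seed). ``ground_truth`` carries each
    subject's true trajectory coefficients, true crossing times and
    duration, true outcome probabilities, and any injected violator type.
    """
    rng = np.random.default_rng(seed)
    races = list(config.race_probs)
    race_p = np.array([config.race_probs[r] for r in races], dtype=float)
    race_p = race_p / race_p.sum()

    n = config.n_subjects
    n_viol = {k: int(round(f * n)) for k, f in config.violator_fracs.items()}
    violator_types = (
        ["few_visits"] * n_viol.get("few_visits", 0)
        + ["no_low_egfr"] * n_viol.get("no_low_egfr", 0)
        + ["non_decline"] * n_viol.get("non_decline", 0)
    )
    violator_types += [""] * (n - len(violator_types))
    rng.shuffle(violator_types)

    visit_rows, subject_rows, truth_rows = [], [], []
    for i in range(n):
        sid = f"S{i:04d}"
        race = races[rng.choice(len(races), p=race_p)]
        sex = "female" if rng.random() < config.female_prob else "male"
        cp = np.asarray(config.cause_probs_by_race[race], dtype=float)
        cause = CAUSES[rng.choice(3, p=cp / cp.sum())]
        age0 = rng.uniform(*config.entry_age_range)
        violator = violator_types[i]

        lead = config.lead_in_years + rng.uniform(-config.lead_in_jitter, config.lead_in_jitter)
        thr = config.krt_threshold_egfr + config.krt_threshold_offset_by_race.get(race, 0.0)

        if violator == "no_low_egfr":
            # declining but staying well above 30 under any equation
            a, b, c = 52.0 + rng.normal(0, 2), -1.5, 0.0
            krt_date = None
        elif violator == "non_decline":
            a, b, c = 28.0 + rng.normal(0, 1), 3.0, 0.0
            krt_date = None
        else:
            # trajectory built on a "crossing clock" tau with tau=0 at the
            # 30-crossing: p(tau) = 30 + b_x tau + c tau², p(d) = 10, so the
            # drawn duration d is the exact ground-truth months 30 -> 10
            c = max(0.0, float(rng.normal(config.curvature_mean, config.curvature_sd)))
            mean_d = config.duration_mean_months_by_race[race]
            shift = config.duration_shift_months
            sd = config.duration_sd_months
            shape = ((mean_d - shift) / sd) ** 2
            scale = sd * sd / (mean_d - shift)
            d_months = shift + rng.gamma(shape, scale)
            if c > 1e-9:  # decline must still be downward at the 10-crossing
                d_months = min(d_months, 0.95 * math.sqrt(20.0 / c) * 12.0)
            d = d_months / 12.0
            b_x = -20.0 / d - c * d

            tau_thr = _downward_root(30.0, b_x, c, thr)
            pt_draw = rng.uniform(0.0, 0.8)  # preemptive KRT precedes the 10-crossing
            tau_10 = d
            # KRT timing decided after outcomes below; both variants prepared here

        # outcomes drawn from the configured logistic model in TRUE years
        if violator in ("no_low_egfr", "non_decline"):
            years = 0.0
        else:
            years = d
        flags, probs = {}, {}
        for outc, (b0, logor) in config.outcome_model.items():
            p = 1.0 / (1.0 + math.exp(-(b0 + logor * years)))
            probs[outc] = p
            flags[outc] = int(rng.random() < p)

        if violator not in ("no_low_egfr", "non_decline"):
            if flags["preemptive_transplant"]:
                krt_tau = max(0.1, tau_10 - pt_draw)
            else:
                krt_tau = (tau_thr if tau_thr is not None else tau_10) + rng.uniform(0.0, 0.25)
            # observation starts `lead` years before KRT, capped so the first
            # visit's true eGFR stays below 90 (a CKD cohort, not healthy kids)
            tau_start = krt_tau - lead
            if 30.0 + b_x * tau_start + c * tau_start**2 > 90.0:
                tau_start = _downward_root(30.0, b_x, c, 90.0)
            # shift the polynomial onto the subject clock t = tau - tau_start
            a = 30.0 + b_x * tau_start + c * tau_start**2
            b = b_x + 2.0 * c * tau_start
            krt_date = krt_tau - tau_start

        t30 = _downward_root(a, b, c, 30.0)
        t10 = _downward_root(a, b, c, 10.0)
        true_months = 12.0 * (t10 - t30) if (t30 is not None and t10 is not None) else float("nan")

        # visit schedule: ~6-monthly with jitter, strictly pre-KRT
        times = [0.0]
        while True:
            nxt = times[-1] + max(0.15, config.visit_interval + rng.normal(0, config.visit_jitter_sd))
            if krt_date is not None and nxt >= krt_date:
                break
            if krt_date is None and nxt > lead:  # non-crossers observed over
                break                            # the same few-year window
            if a + b * nxt + c * nxt * nxt <= max(thr, 1.0):
                break
            times.append(nxt)
        if violator == "few_visits":
            times = times[:2]

        for t in times:
            age = age0 + t
            height = _height_cm(age, sex)
            egfr_true = a + b * t + c * t * t
            scr_clean = invert_scheme_scr(egfr_true, age, sex, height, "schwartz_ckdepi")
            noise_sd = math.sqrt(math.log(1.0 + config.scr_noise_cv**2))
            scr = scr_clean * rng.lognormal(-0.5 * noise_sd**2, noise_sd) if config.scr_noise_cv > 0 else scr_clean
            urine_kind, urine_value = "", ""
            if rng.random() >= config.urine_missing_prob:
                mu, sg = config.albuminuria_by_cause[cause]
                acr = float(rng.lognormal(mu, sg))
                kinds = list(config.urine_kind_probs)
                kind = kinds[rng.choice(len(kinds), p=np.array([config.urine_kind_probs[k] for k in kinds]))]
                if kind == "acr":
                    urine_kind, urine_value = "acr", f"{acr:.4f}"
                elif kind == "pcr":
                    urine_kind, urine_value = "pcr", f"{1.8 * acr:.4f}"
                else:
                    urine_kind, urine_value = "dipstick", _acr_to_dipstick(acr)
            visit_rows.append(
                {"subject_id": sid, "visit_time": t, "age": age,
                 "height": height, "scr": scr,
                 "urine_kind": urine_kind, "urine_value": urine_value}
            )

        transplanted = flags["preemptive_transplant"] or flags["living_donor_transplant"]
        if flags["preemptive_transplant"]:
            modality = "preemptive_transplant"
        else:
            modality = ("in_center_hd", "pd", "home_hd")[rng.choice(3, p=[0.663, 0.315, 0.022])]
        if flags["preemptive_waitlisting"]:
            waitlist = "preemptive"
        else:
            waitlist = "post_dialysis" if rng.random() < 0.44 else "not_waitlisted"
        donor = ""
        if transplanted:
            donor = "living" if flags["living_donor_transplant"] else "deceased"

        subject_rows.append(
            {"subject_id": sid, "sex": sex, "race_ethnicity": race, "ckd_cause": cause,
             "entry_age": round(age0, 4),
             "krt_date": round(krt_date, 6) if krt_date is not None else "",
             "krt_modality": modality, "waitlist_status": waitlist, "donor_type": donor}
        )
        truth_rows.append(
            {"subject_id": sid, "a": a, "b": b, "c": c,
             "t30_true": t30, "t10_true": t10, "true_low_egfr_months": true_months,
             "violator_type": violator,
             **{f"p_{k}": v for k, v in probs.items()},
             **{f"y_{k}": v for k, v in flags.items()}}
        )

    visits = pd.DataFrame(visit_rows)
    subjects = pd.DataFrame(subject_rows)
    subjects["krt_date"] = pd.to_numeric(subjects["krt_date"], errors="coerce")
    truth = pd.DataFrame(truth_rows)
    return visits, subjects, truth


def make_table4_fixture() -> pd.DataFrame:
    """A 333-row subject table reproducing the published outcome margins.

    Synthetic: the paper prints only per-race *marginal* counts (race and
    cause-of-CKD composition, waitlist status, KRT modality, donor type
    among transplants); the joint assignment of categories to rows here is
    an invented deterministic round-robin. Every printed marginal count is
    reproduced exactly; the joint structure carries no information.
    """
    blocks = {
        # race: (n, waitlist(not, preemptive, post), krt(ichd, home, pd, pt),
        #        donor among pt (living, deceased, unknown), cause(glom, cakut, other))
        "White": (160, (20, 133, 7), (46, 1, 21, 92), (65, 24, 3), (23, 51, 86)),
        "Black": (72, (11, 48, 13), (37, 1, 16, 18), (4, 10, 4), (23, 18, 31)),
        "Hispanic": (65, (5, 50, 10), (22, 2, 17, 24), (13, 11, 0), (18, 15, 32)),
        "Other": (36, (7, 25, 4), (17, 0, 4, 15), (7, 8, 0), (11, 5, 20)),
    }
    wl_labels = ("not_waitlisted", "preemptive", "post_dialysis")
    krt_labels = ("in_center_hd", "home_hd", "pd", "preemptive_transplant")
    donor_labels = ("living", "deceased", "unknown")
    rows = []
    idx = 0
    for race, (n, wl, krt, donor, cause) in blocks.items():
        assert sum(wl) == n and sum(krt) == n and sum(cause) == n
        assert sum(donor) == krt[3]
        wl_seq = [lab for lab, k in zip(wl_labels, wl) for _ in range(k)]
        cause_seq = [lab for lab, k in zip(CAUSES, cause) for _ in range(k)]
        # preemptive-transplant rows first so donors fill them exactly
        krt_seq = ["preemptive_transplant"] * krt[3] + [
            lab for lab, k in zip(krt_labels[:3], krt[:3]) for _ in range(k)
        ]
        donor_seq = [lab for lab, k in zip(donor_labels, donor) for _ in range(k)]
        donor_seq += [""] * (n - len(donor_seq))
        for j in range(n):
            rows.append(
                {"subject_id": f"T{idx:04d}", "race_ethnicity": race,
                 "ckd_cause": cause_seq[j], "waitlist_status": wl_seq[j],
                 "krt_modality": krt_seq[j], "donor_type": donor_seq[j],
                 "sex": "female" if j % 3 == 0 else "male"}
            )
            idx += 1
    return pd.DataFrame(rows)
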