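"""Cross-scheme bootstrap contrasts and transplant-access models.

Race contrasts in low-eGFR time are estimated separately under the
Schwartz/CKD-EPI scheme and the U25 scheme; the two regressions share no
likelihood, so the sampling distribution of the *difference* in their
coefficients is obtained by a cluster bootstrap: subjects are resampled
with replacement (all visits of a sampled subject move together, preserving
the within-subject correlation the mixed model exists for), the entire
pipeline — eGFR computation, mixed-model fit, crossing times, race OLS —
is rerun under both schemes on each replicate, and percentile confidence
intervals are read off the per-replicate coefficient differences.

Transplant-access outcomes (preemptive transplant, living-donor transplant,
preemptive waitlisting) are modelled by maximum-likelihood logistic
regression on years spent with eGFR 10–30, with sequential adjustment
tiers, and a joint Wald test probes exposure × race interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .egfr import Scheme, compute_egfr_table
from .exposure import derive_crossing_summaries, race_effect_regression
from .trajectory import ConvergenceError, fit_trajectory_lmm

ADJUSTMENT_SETS = ("none", "demographic", "demographic+albuminuria")
OUTCOMES = ("preemptive_transplant", "living_donor_transplant", "preemptive_waitlisting")


@dataclass
class BootstrapContrast:
    contrast_label: str
    delta_beta: float  # months: scheme A beta - scheme B beta
    ci_low: float
    ci_high: float
    n_reps: int
    n_dropped: int
    seed: int
    per_rep_values: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "per_rep_values"}
        return d


@dataclass
class OutcomeEffect:
    outcome: str
    scheme: str
    adjustment_set: str
    or_per_year: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    n_dropped_missing_acr: int = 0

    def to_dict(self) -> dict:
        return vars(self).copy()


def scheme_race_betas(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    scheme: Scheme,
    outcome_field: str = "low_egfr_months",
) -> dict[str, float]:
    """eGFR → LMM → crossing times → race OLS under one scheme.

    Returns ``{contrast_label: beta_months}``. Time is re-originated at each
    subject's first visit that yields an eGFR under the scheme.
    """
    table, _ = compute_egfr_table(visits, subjects, scheme)
    origin = table.groupby("subject_id")["visit_time"].transform("min")
    long = table.assign(time=table["visit_time"] - origin)
    origin_by_id = table.groupby("subject_id")["visit_time"].min()

    fit = fit_trajectory_lmm(long, scheme=scheme)
    # KRT dates move onto each subject's model clock
    subj = subjects.copy()
    if "krt_date" in subj:
        subj["krt_date"] = subj["krt_date"] - subj["subject_id"].map(origin_by_id)
    summaries = derive_crossing_summaries(fit, subj)
    effects = race_effect_regression(summaries, subjects, outcome_field, scheme=scheme)
    return {e.contrast_label: e.beta_months for e in effects}


def _resample_clusters(visits, subjects, rng):
    ids = subjects["subject_id"].to_numpy()
    pick = rng.integers(0, len(ids), size=len(ids))
    vis_by = {sid: g for sid, g in visits.groupby("subject_id")}
    new_vis, new_subj = [], []
    for j, k in enumerate(pick):
        sid = ids[k]
        nid = f"{sid}__b{j}"
        s = subjects.iloc[[k]].copy()
        s["subject_id"] = nid
        v = vis_by[sid].copy()
        v["subject_id"] = nid
        new_subj.append(s)
        new_vis.append(v)
    return (
        pd.concat(new_vis, ignore_index=True),
        pd.concat(new_subj, ignore_index=True),
    )


def bootstrap_equation_contrast(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    schemes: tuple[Scheme, Scheme] = ("schwartz_ckdepi", "u25"),
    n_reps: int = 1000,
    seed: int = 0,
    outcome_field: str = "low_egfr_months",
    max_drop_frac: float = 0.05,
) -> list[BootstrapContrast]:
    """Cluster-bootstrap CIs for scheme-A-minus-scheme-B race coefficients.

    Each replicate resamples whole subjects with replacement and reruns the
    full pipeline under both schemes. Replicates whose mixed model fails to
    converge (or loses a race group) are dropped and counted; more than
    ``max_drop_frac`` dropped is a hard error.
    """
    rng = np.random.default_rng(seed)
    point_a = scheme_race_betas(visits, subjects, schemes[0], outcome_field)
    point_b = scheme_race_betas(visits, subjects, schemes[1], outcome_field)
    labels = sorted(set(point_a) & set(point_b))
    reps: dict[str, list[float]] = {lab: [] for lab in labels}
    n_dropped = 0
    for _ in range(n_reps):
        bv, bs = _resample_clusters(visits, subjects, rng)
        try:
            ba = scheme_race_betas(bv, bs, schemes[0], outcome_field)
            bb = scheme_race_betas(bv, bs, schemes[1], outcome_field)
            for lab in labels:
                reps[lab].append(ba[lab] - bb[lab])
        except (ConvergenceError, ValueError, KeyError):
            n_dropped += 1
    if n_reps and n_dropped / n_reps > max_drop_frac:
        raise RuntimeError(
            f"{n_dropped}/{n_reps} bootstrap replicates dropped "
            f"(> {max_drop_frac:.0%}); bootstrap unreliable"
        )
    out = []
    for lab in labels:
        vals = np.asarray(reps[lab])
        lo, hi = (
            (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
            if len(vals)
            else (float("nan"), float("nan"))
        )
        out.append(
            BootstrapContrast(
                contrast_label=lab,
                delta_beta=point_a[lab] - point_b[lab],
                ci_low=lo,
                ci_high=hi,
                n_reps=len(vals),
                n_dropped=n_dropped,
                seed=seed,
                per_rep_values=vals,
            )
        )
    return out


def _adjustment_terms(adjustment_set: str, include_race: bool) -> list[str]:
    if adjustment_set == "none":
        return []
    terms = ["age_at_entry", "C(sex)", "C(ckd_cause)"]
    if include_race:
        terms.append("C(race_ethnicity)")
    if adjustment_set == "demographic+albuminuria":
        terms.append("log_acr")
    elif adjustment_set != "demographic":
        raise ValueError(f"unknown adjustment_set {adjustment_set!r}")
    return terms


def fit_outcome_logistic(
    data: pd.DataFrame,
    outcome: str,
    adjustment_set: str = "none",
    scheme: str = "",
    include_race: bool = True,
    exposure: str = "exposure_years",
) -> OutcomeEffect:
    """Logistic model of a binary transplant-access outcome on low-eGFR years.

    ``data`` is subject-level with the exposure already in years. Adjustment
    tiers: ``none``; ``demographic`` (age at first record, sex, CKD cause,
    and race); ``demographic+albuminuria`` adds log-transformed ACR,
    complete-case, with the dropped count reported on the estimate.
    """
    df = data.copy()
    y = df[outcome]
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has no variation (all {y.iloc[0]})")
    n_dropped = 0
    terms = _adjustment_terms(adjustment_set, include_race)
    if "log_acr" in terms:
        n_before = len(df)
        df = df.dropna(subset=["log_acr"])
        n_dropped = n_before - len(df)
    formula = f"{outcome} ~ {exposure}" + "".join(f" + {t}" for t in terms)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = smf.logit(formula, df).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise ValueError(
                f"perfect separation fitting {outcome!r} on {exposure!r} "
                f"(+ {terms}): {exc}"
            ) from exc
    conf = res.conf_int(alpha=0.05)
    return OutcomeEffect(
        outcome=outcome,
        scheme=scheme,
        adjustment_set=adjustment_set,
        or_per_year=float(np.exp(res.params[exposure])),
        ci_low=float(np.exp(conf.loc[exposure, 0])),
        ci_high=float(np.exp(conf.loc[exposure, 1])),
        p=float(res.pvalues[exposure]),
        n_used=int(res.nobs),
        n_dropped_missing_acr=n_dropped,
    )


def interaction_test(
    data: pd.DataFrame,
    outcome: str,
    exposure: str = "exposure_years",
    race_col: str = "race_ethnicity",
) -> float:
    """Joint Wald p-value for exposure × race interaction in the logistic model.

    Race groups with fewer than 2 subjects are dropped with a warning; a
    single remaining group makes the interaction unestimable and is an error.
    """
    df = data.copy()
    counts = df[race_col].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"dropping race groups with < 2 subjects: {small}")
        df = df[~df[race_col].isin(small)]
    if df[race_col].nunique() < 2:
        raise ValueError("interaction test needs >= 2 race groups")
    formula = f"{outcome} ~ {exposure} * C({race_col})"
    res = smf.logit(formula, df).fit(disp=0)
    names = [n for n in res.params.index if ":" in n and exposure in n]
    constraint = ", ".join(f"{n} = 0" for n in names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=FutureWarning)
        wt = res.wald_test(constraint, scalar=True)
    return float(wt.pvalue)
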