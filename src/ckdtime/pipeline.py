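"""End-to-end orchestration: data → eligibility → eGFR → trajectories →
durations → race contrasts → bootstrap → outcome models → reports.

Everything downstream of the input is a pure function of
(:class:`PipelineConfig`, seed); two runs with the same pair produce
byte-identical report files, which the manifest records with content
hashes so the claim is checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import apply_eligibility
from .egfr import SCHEMES, Scheme, compute_egfr_table
from .exposure import derive_crossing_summaries, race_effect_regression
from .inference import (
    ADJUSTMENT_SETS,
    OUTCOMES,
    bootstrap_equation_contrast,
    fit_outcome_logistic,
    interaction_test,
)
from .reporting import summarize_characteristics, summarize_outcomes
from .simulate import GeneratorConfig, generate_cohort
from .trajectory import fit_trajectory_lmm
from .urine import UrineMeasure, log_albuminuria, select_albuminuria

STAGES = (
    "ingest",
    "eligibility",
    "egfr",
    "trajectory",
    "durations",
    "race_contrasts",
    "bootstrap",
    "outcomes",
)


@dataclass
class PipelineConfig:
    visits_csv: Optional[str] = None
    subjects_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    schemes: tuple[Scheme, ...] = SCHEMES
    n_bootstrap: int = 1000
    seed: Optional[int] = None
    adjustment_sets: tuple[str, ...] = ADJUSTMENT_SETS
    include_race_adjustment: bool = True
    outdir: str = "ckdtime_out"

    def __post_init__(self) -> None:
        from_files = self.visits_csv is not None or self.subjects_csv is not None
        if from_files == (self.generator is not None):
            raise ValueError("exactly one input source: CSV paths or a generator config")
        if from_files and (self.visits_csv is None or self.subjects_csv is None):
            raise ValueError("both visits_csv and subjects_csv are required")
        if self.seed is None and (self.generator is not None or self.n_bootstrap > 0):
            raise ValueError("seed is required when any stochastic stage is enabled")


def subject_albuminuria(visits: pd.DataFrame, subjects: pd.DataFrame) -> pd.Series:
    """log(ACR + 1) covariate per subject, anchored at each subject's model
    time origin (their first visit)."""
    values = {}
    entry_age = visits.groupby("subject_id")["age"].min()
    for sid, g in visits.groupby("subject_id"):
        measures = []
        for row in g.itertuples(index=False):
            kind = getattr(row, "urine_kind", "")
            if not isinstance(kind, str) or kind == "" or pd.isna(kind):
                continue
            raw = row.urine_value
            value = raw if kind == "dipstick" else float(raw)
            measures.append(UrineMeasure(kind=kind, value=value, measured_time=float(row.visit_time)))
        t0 = float(g["visit_time"].min())
        acr = select_albuminuria(measures, t_origin=t0, age_at_origin=float(entry_age[sid]))
        values[sid] = log_albuminuria(acr)
    return pd.Series(values, name="log_acr", dtype=float)


def build_outcome_table(
    visits: pd.DataFrame, subjects: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Subject-level analysis table for the transplant-access models."""
    df = subjects.merge(
        summaries[["subject_id", "low_egfr_months"]], on="subject_id"
    ).dropna(subset=["low_egfr_months"])
    df["exposure_years"] = df["low_egfr_months"] / 12.0
    df["preemptive_transplant"] = (df["krt_modality"] == "preemptive_transplant").astype(int)
    df["living_donor_transplant"] = (
        df["donor_type"].fillna("").astype(str) == "living"
    ).astype(int)
    df["preemptive_waitlisting"] = (df["waitlist_status"] == "preemptive").astype(int)
    if "entry_age" not in df:
        entry = visits.groupby("subject_id")["age"].min().rename("entry_age")
        df = df.merge(entry, left_on="subject_id", right_index=True)
    df["age_at_entry"] = df["entry_age"]
    acr = subject_albuminuria(visits, subjects)
    df["log_acr"] = df["subject_id"].map(acr)
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write the report bundle, return it as a dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    bundle: dict = {}

    def done(stage: str, status: str = "completed", **extra) -> None:
        manifest["stages"].append({"stage": stage, "status": status, **extra})

    # 1. ingest or simulate
    if config.generator is not None:
        visits, subjects, truth = generate_cohort(config.generator, seed=config.seed)
        bundle["ground_truth"] = truth
    else:
        visits = pd.read_csv(config.visits_csv)
        subjects = pd.read_csv(config.subjects_csv)
    done("ingest", n_subjects=len(subjects), n_visits=len(visits))

    # 2. eligibility
    visits, subjects, consort = apply_eligibility(visits, subjects)
    bundle["consort"] = consort.to_records()
    done("eligibility", n_final=consort.n_final)

    # 3-6. per-scheme: eGFR, mixed model, crossing summaries, race OLS
    fits, summaries_by_scheme, skipped_counts = {}, {}, {}
    effects = []
    for scheme in config.schemes:
        table, skipped = compute_egfr_table(visits, subjects, scheme)
        skipped_counts[scheme] = len(skipped)
        origin = table.groupby("subject_id")["visit_time"].transform("min")
        long = table.assign(time=table["visit_time"] - origin)
        origin_by_id = table.groupby("subject_id")["visit_time"].min()
        fit = fit_trajectory_lmm(long, scheme=scheme)
        fits[scheme] = fit
        subj_clock = subjects.copy()
        if "krt_date" in subj_clock:
            subj_clock["krt_date"] = subj_clock["krt_date"] - subj_clock["subject_id"].map(origin_by_id)
        summaries = derive_crossing_summaries(fit, subj_clock)
        summaries_by_scheme[scheme] = summaries
        for outcome_field in ("low_egfr_months", "months_30_to_krt"):
            effects.extend(
                e.to_dict()
                for e in race_effect_regression(summaries, subjects, outcome_field, scheme=scheme)
            )
    done("egfr", skipped=skipped_counts)
    done("trajectory", fits={s: fits[s].to_dict() for s in fits})
    done("durations", median_low_egfr_months={
        s: float(summaries_by_scheme[s]["low_egfr_months"].median()) for s in summaries_by_scheme
    })
    done("race_contrasts", n_estimates=len(effects))
    bundle["race_effects"] = effects

    # 7. bootstrap contrast across schemes
    if config.n_bootstrap > 0 and len(config.schemes) == 2:
        contrasts = bootstrap_equation_contrast(
            visits, subjects, schemes=tuple(config.schemes),
            n_reps=config.n_bootstrap, seed=config.seed,
        )
        bundle["bootstrap_contrasts"] = [c.to_dict() for c in contrasts]
        done("bootstrap", n_reps=config.n_bootstrap)
    else:
        bundle["bootstrap_contrasts"] = []
        done("bootstrap", status="skipped", reason="n_bootstrap=0 or not two schemes")

    # 8. outcome logistics + interaction tests
    outcome_effects, interactions = [], {}
    for scheme in config.schemes:
        analysis = build_outcome_table(visits, subjects, summaries_by_scheme[scheme])
        for outcome in OUTCOMES:
            for adj in config.adjustment_sets:
                try:
                    eff = fit_outcome_logistic(
                        analysis, outcome, adjustment_set=adj, scheme=scheme,
                        include_race=config.include_race_adjustment,
                    )
                    outcome_effects.append(eff.to_dict())
                except ValueError as exc:
                    outcome_effects.append(
                        {"outcome": outcome, "scheme": scheme, "adjustment_set": adj,
                         "error": str(exc)}
                    )
            try:
                interactions[f"{scheme}:{outcome}"] = interaction_test(analysis, outcome)
            except ValueError as exc:
                interactions[f"{scheme}:{outcome}"] = f"error: {exc}"
    bundle["outcome_effects"] = outcome_effects
    bundle["interaction_p"] = interactions
    done("outcomes", n_models=len(outcome_effects))

    bundle["table1"] = summarize_characteristics(subjects, visits)
    bundle["table4"] = summarize_outcomes(subjects)

    _write_bundle(bundle, summaries_by_scheme, manifest, outdir)
    return {"manifest": manifest, **bundle}


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_bundle(bundle, summaries_by_scheme, manifest, outdir: Path) -> None:
    files = {}
    for scheme, summaries in summaries_by_scheme.items():
        p = outdir / f"crossing_summaries_{scheme}.csv"
        summaries.to_csv(p, index=False)
        files[p.name] = p
    for name in ("consort", "race_effects", "bootstrap_contrasts",
                 "outcome_effects", "interaction_p", "table1", "table4"):
        if name not in bundle:
            continue
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(bundle[name], sort_keys=True, indent=1, default=_json_default))
        files[p.name] = p
    for name, p in files.items():
        manifest["outputs"][name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=_json_default)
    )
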