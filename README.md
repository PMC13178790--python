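# ckdtime

Tools for quantifying **time spent with low eGFR** — between 30 and 10
mL/min/1.73 m² — in children and young adults with advanced chronic kidney
disease, and for relating that time to access to preemptive and
living-donor kidney transplantation.

The window between an eGFR of 30 (when transplant evaluation usually
begins) and 10 (the median eGFR at dialysis start in US children) is the
time a family has to prepare for kidney replacement therapy: identify a
living donor, complete the recipient work-up, get waitlisted. Groups that
progress faster have less of it. `ckdtime` implements the full analysis
chain needed to measure that window from routine serum-creatinine data and
to test its consequences, for biostatisticians and nephrology researchers
working with longitudinal pediatric CKD cohorts.

## What it computes

1. **eGFR estimation** from creatinine under two schemes: the
   clinical-practice dispatch (bedside Schwartz `0.413·height/SCr` under
   age 18, CKD-EPI 2021 at 18+) and the CKiD U25 equation
   (`k(age,sex)·height/SCr`) across all ages 1–25.
2. **Eligibility filtering** with consort accounting: ≥ 3 pre-KRT
   creatinines, ≥ 1 bedside-Schwartz eGFR < 30 before KRT, net eGFR
   decline, age < 25 at entry.
3. **Trajectory modelling** by a linear mixed model,

   `eGFR_ij = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)·t_ij + β₂·t_ij² + ε_ij`,

   with subject-specific random intercepts and slopes `(b₀ᵢ,b₁ᵢ) ~ N(0, G)`
   (REML; unstructured G; the quadratic is a fixed effect only).
4. **Threshold-crossing times**: each subject's predicted curve (fixed
   effects + BLUPs) is inverted analytically for its downward crossings of
   30 and 10; `low_egfr_months = 12·(t₁₀ − t₃₀)`, with a sensitivity
   variant anchored at the observed KRT start date.
5. **Race contrasts** in those durations by OLS (White reference), and a
   **cluster bootstrap** (resampling whole subjects, rerunning the entire
   pipeline under both equation schemes per replicate) for the
   cross-scheme difference in coefficients.
6. **Transplant-access models**: logistic regressions of preemptive
   transplant, living-donor transplant and preemptive waitlisting on years
   with low eGFR, with sequential adjustment and exposure × race
   interaction tests.
7. A **synthetic cohort generator** with known ground truth (true
   trajectories, true crossing times, true outcome probabilities), since
   the kind of registry data this targets cannot usually be shared.

## Worked example

```python
import ckdtime as ck

visits, subjects, truth = ck.generate_cohort(ck.GeneratorConfig(n_subjects=333), seed=7)
v, s, consort = ck.apply_eligibility(visits, subjects)
table, _ = ck.compute_egfr_table(v, s, "schwartz_ckdepi")
origin = table.groupby("subject_id")["visit_time"].transform("min")
fit = ck.fit_trajectory_lmm(table.assign(time=table["visit_time"] - origin))
summaries = ck.derive_crossing_summaries(fit, s)
print(summaries["low_egfr_months"].median())
for eff in ck.race_effect_regression(summaries, s):
    print(eff.contrast_label, eff.beta_months, (eff.ci_low, eff.ci_high), eff.p_value)
```

prints (seed 7):

```
28.0
Black vs White -4.9 months [-8.0, -1.8]  p=0.002
Hispanic vs White -0.4 months [-3.6, 2.7]  p=0.793
Other vs White -2.1 months [-6.5, 2.3]  p=0.339
```

The cohort spends a median of 28 months with eGFR between 10 and 30; Black
subjects are estimated to spend about 5 months less of that preparation
time than White subjects (the generator's configured truth for this
contrast is −6 months). The `examples/` directory has one short script per
capability — equations, cohort-to-durations, outcome models, the bootstrap
scheme contrast, and descriptive tables — each printing its numbers with a
line on what they mean. A thin CLI mirrors the stages
(`ckdtime simulate|filter|fit|durations|contrast|outcomes|report|all`).

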