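"""Odds of preemptive/living-donor transplant per year with low eGFR.

Fits the sequential logistic models: unadjusted; adjusted for age, sex,
race and cause of CKD; and additionally for log-transformed albuminuria
(the harmonized ACR covariate). A joint Wald test checks whether the
exposure effect differs by race/ethnicity.
"""

import ckdtime as ck
from ckdtime.pipeline import build_outcome_table

visits, subjects, _ = ck.generate_cohort(ck.GeneratorConfig(n_subjects=333), seed=11)
v, s, _ = ck.apply_eligibility(visits, subjects)
table, _sk = ck.compute_egfr_table(v, s, "schwartz_ckdepi")
origin = table.groupby("subject_id")["visit_time"].transform("min")
fit = ck.fit_trajectory_lmm(table.assign(time=table["visit_time"] - origin))
summaries = ck.derive_crossing_summaries(fit, s)
analysis = build_outcome_table(v, s, summaries)

for outcome in ("preemptive_transplant", "living_donor_transplant", "preemptive_waitlisting"):
    print(outcome)
    for adj in ("none", "demographic", "demographic+albuminuria"):
        eff = ck.fit_outcome_logistic(analysis, outcome, adjustment_set=adj)
        note = f" ({eff.n_dropped_missing_acr} dropped, no ACR)" if eff.n_dropped_missing_acr else ""
        print(f"  {adj:26s} OR/yr {eff.or_per_year:5.2f} "
              f"[{eff.ci_low:4.2f}, {eff.ci_high:4.2f}]  p={eff.p:.3f}{note}")
    p_int = ck.interaction_test(analysis, outcome)
    print(f"  exposure x race interaction p = {p_int:.3f}")

print("\nOR > 1 means each extra year spent with eGFR 10-30 raises the odds of")
print("the outcome; the generator's truth is 1.45/yr (preemptive transplant),")
print("1.42/yr (living donor), and no effect on preemptive waitlisting.")
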