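"""Synthetic cohort -> eligibility -> mixed model -> low-eGFR durations.

Generates a study-sized cohort with a configured -6 month Black-vs-White
difference in true time from eGFR 30 to 10, filters it the way the study
selected patients, fits the quadratic random-intercept/random-slope mixed
model, inverts each subject's predicted trajectory for the 30- and
10-crossings, and reports the race contrast the pipeline recovers.
"""

import ckdtime as ck

visits, subjects, truth = ck.generate_cohort(ck.GeneratorConfig(n_subjects=333), seed=7)
v, s, consort = ck.apply_eligibility(visits, subjects)
print("consort accounting:")
for step in consort.to_records():
    print(f"  {step['filter_name']:28s} {step['n_before']:4d} -> {step['n_after']:4d}"
          f"  (excluded {step['n_excluded']})")

table, skipped = ck.compute_egfr_table(v, s, "schwartz_ckdepi")
origin = table.groupby("subject_id")["visit_time"].transform("min")
fit = ck.fit_trajectory_lmm(table.assign(time=table["visit_time"] - origin),
                            scheme="schwartz_ckdepi")
print(f"\npopulation curve: eGFR = {fit.beta0:.1f} {fit.beta1:+.2f} t {fit.beta2:+.2f} t^2"
      f"   (residual sd {fit.sigma2 ** 0.5:.2f})")

summaries = ck.derive_crossing_summaries(fit, s)
print(f"median months with eGFR 10-30: {summaries['low_egfr_months'].median():.1f}")

for eff in ck.race_effect_regression(summaries, s):
    print(f"  {eff.contrast_label:18s} {eff.beta_months:+6.1f} months "
          f"[{eff.ci_low:.1f}, {eff.ci_high:.1f}]  p={eff.p_value:.3f}")

print("\nThe Black-vs-White coefficient estimates the difference in months of")
print("advanced-CKD time available for transplant preparation (truth: -6.0).")
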