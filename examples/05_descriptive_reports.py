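"""Journal-style descriptive tables from the printed-counts fixture.

The 333-row fixture reproduces the published marginal counts of the study
cohort (race composition, waitlist status, KRT modality, donor type among
transplants, cause of CKD); the report layer turns counts into column
percentages with the journal's rounding rule and group-comparison p-values.
"""

import ckdtime as ck

fx = ck.make_table4_fixture()
rep = ck.summarize_outcomes(fx)
chars = ck.summarize_characteristics(fx)

krt = rep["krt_modality"]["levels"]["preemptive_transplant"]
wl = rep["waitlisted"]["levels"]
donor = rep["donor_type_among_transplants"]["levels"]["living"]

print(f"cohort n = {rep['n_total']}; Black race {chars['race_pct']['Black']}%;"
      f" glomerular cause {chars['cause_of_ckd']['levels']['glomerular']['total_pct']}%")
print(f"preemptive transplant: {krt['total_n']} ({krt['total_pct']}%)"
      f"  — White {krt['White']['pct']}%, Black {krt['Black']['pct']}%")
print(f"preemptively waitlisted: {wl['preemptive']['total_n']} ({wl['preemptive']['total_pct']}%);"
      f" waitlisted after dialysis: {wl['post_dialysis']['total_pct']}%")
print(f"living donors among transplants: {donor['total_n']} ({donor['total_pct']}%)"
      f" — {donor['White']['pct']}% of White transplants")
print(f"KRT modality p-value across race: {rep['krt_modality']['p_value']:.2g}")

print("\nEvery percentage re-derives from its counts (nearest integer, ties")
print("away from zero) — the same audit the test suite runs automatically.")
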