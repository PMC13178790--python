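"""Estimate GFR for one patient under the three creatinine equations.

A 17.5-year-old with serum creatinine 2.0 mg/dL is about to turn 18: under
the clinical-practice scheme their eGFR jumps from the bedside Schwartz
value to the CKD-EPI 2021 value at the birthday, while the CKiD U25
equation gives a single continuous series across the same ages.
"""

import ckdtime as ck
from ckdtime.egfr import VisitRecord

height_cm, scr, sex = 170.0, 2.0, "male"

for age in (17.5, 17.9, 18.0, 18.5):
    visit = VisitRecord("p1", age=age, scr=scr, visit_time=0.0, height=height_cm)
    practice = ck.egfr_dispatch(visit, sex, "schwartz_ckdepi")
    u25 = ck.egfr_dispatch(visit, sex, "u25")
    print(f"age {age:5.1f}: practice scheme {practice:6.2f}   U25 {u25:6.2f}  mL/min/1.73m2")

print()
print("The practice scheme has a step discontinuity at the 18th birthday")
print("(Schwartz -> CKD-EPI 2021), mirroring how eGFR was reported clinically;")
print("the U25 equation changes smoothly across the same ages.")
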