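# Methods

## The estimand

For a subject whose kidney function declines through advanced CKD, the
quantity of interest is the time their eGFR spends between 30 and 10
mL/min/1.73 m² — the window available to prepare for kidney replacement
therapy (KRT). Observed eGFR values are noisy and irregularly timed, so
the window is not read off raw data: a mixed model smooths each subject's
trajectory, and the smoothed curve is inverted for the two threshold
crossings. Group contrasts (here, race/ethnicity) are then estimated on
the subject-level durations, and the durations in turn serve as the
exposure in logistic models of transplant access.

## eGFR estimation

Two schemes are implemented, both creatinine-based:

* **Clinical practice** (`schwartz_ckdepi`): bedside Schwartz,
  eGFR = 0.413 × height(cm)/SCr, at ages < 18; the race-free CKD-EPI 2021
  equation (scale 142, sex-specific κ/α, spline exponent −1.200, age
  factor 0.9938, female factor 1.012) at 18+. The switch happens at the
  18th birthday mid-follow-up, producing a deliberate step discontinuity —
  this mirrors how eGFR was actually reported for these patients.
* **CKiD U25** (`u25`): eGFR = k(age, sex) × height(m)/SCr with the
  published piecewise k table (e.g. males 1–12 y: 39.0 × 1.008^(age−12);
  12–18 y: 39.0 × 1.045^(age−12); 18–25 y: 50.8), evaluated at the exact
  decimal age, over the whole range [1, 25).

All equation constants live in `ckdtime/data/equations.yaml`; a corrected
transcription or alternative constants never touch code. Heights are
validated against a plausibility window (40–220 cm) with warnings rather
than hard errors; decimal age is taken as exact days/365.25 when computed
from dates. No cystatin C pathway is provided.

## Urine-protein harmonization

Albuminuria enters outcome models as log(ACR + 1) mg/g (the +1 admits
zeros). Dipstick categories map to ACR through a monotone ordinal table,
and PCR converts to/from ACR through an age-grouped log-linear model
PCR = exp(b₀)·ACR^b₁. **The shipped dipstick table and conversion
coefficients are synthetic defaults** with the right functional form and
monotonicity — published validated coefficients should be dropped into the
YAML config for real analyses. The covariate value is the most recent
measure at or before the model's time origin, else the nearest measure in
time (ties prefer the earlier, pre-origin measure, then input order).

## Eligibility

Filters apply in a fixed order so the consort log is reproducible:
(a) ≥ 3 pre-KRT creatinines (strictly before the KRT date; KRT-day values
excluded); (b) ≥ 1 pre-KRT bedside-Schwartz eGFR < 30 — Schwartz is used
for this criterion at every age regardless of the analysis scheme;
(c) final pre-KRT eGFR below the first; (d) age < 25 at entry (follow-up
past 25 is retained). The log's arithmetic
(n_after = n_before − n_excluded, chained) is asserted on every run.

## Trajectory model

eGFR_ij = (β₀+b₀ᵢ) + (β₁+b₁ᵢ) t_ij + β₂ t_ij² + ε_ij, with
(b₀ᵢ, b₁ᵢ) ~ N(0, G) unstructured and ε ~ N(0, σ²), fitted by REML
(statsmodels MixedLM; ML available via the `reml` flag). Time is years
since the subject's first record that yields an eGFR under the scheme in
use; crossing-time *differences* are invariant to that origin choice, and
the test suite asserts it. There is no random quadratic term, the model is
unadjusted (no covariates — group differences are read off the predicted
trajectories downstream, since candidate covariates like CKD cause are
mediators of the differences of interest), and eGFR is modelled on the raw
scale. Per-subject curves combine fixed effects with BLUPs. A singular G
is returned with a flag and warning; optimizer failure raises with the
trace attached. At least two subjects are required.

## Crossing times and durations

For a + b t + c t², downward crossings of a threshold solve the quadratic
analytically; a root counts only if the local slope is negative. The
search horizon is 30 years (beyond that a trajectory is non-crossing —
this affects only pathological fits). t₃₀ is searched from −horizon
because a subject may enter observation already below 30; durations are
differences and remain well-defined. Subjects whose curve never reaches
10 (upward-curving vertex above the threshold) are flagged `only30` and
excluded from duration regressions — the decline filter makes them rare.
Race contrasts use OLS with model-based standard errors; the bootstrap is
reserved for the cross-scheme comparison, where no joint likelihood
exists.

## Cluster bootstrap for the cross-scheme contrast

Subjects (with all their visits) are resampled with replacement; each
replicate reruns eGFR computation → mixed model → crossings → race OLS
under both schemes and records the coefficient difference. Percentile 95%
intervals summarize the replicates. The resampling unit is the subject —
a residual bootstrap would destroy the within-subject correlation the
mixed model exists to handle. Replicates whose mixed model fails to
converge (or that lose a race group entirely) are dropped and counted;
more than 5% dropped is a hard error. The analysis default is 1,000
replications; tests and the acceptance script use 6–60 replications on
smaller cohorts, which exercises the same code path at tractable cost.

## Outcome models

Logistic regressions of three binary outcomes (preemptive transplant,
living-donor transplant, preemptive waitlisting) on years with eGFR
10–30. Adjustment tiers: none; demographic (age at first record, sex, CKD
cause, and race — race is included by default with a switch, since the
adjusted models are described both with and without it); demographic plus
log-ACR (complete-case, with the dropped count reported). Perfect
separation raises a named error rather than returning a divergent
estimate. The interaction test is a joint Wald test that all
exposure × race product terms are zero (per-race groups with < 2 subjects
are dropped with a warning); per-term p-values are available from the
underlying fit.

## Synthetic cohort generator

The generator emulates the data streams the analysis assumes, with ground
truth recorded for every subject:

* **Trajectories.** Each regular subject gets a quadratic eGFR curve
  built on a clock anchored at its 30-crossing: the true duration D
  (months from 30 to 10) is drawn from a shifted gamma
  (shift 6, sd 10 months) with race-specific means — White 30, Black 24,
  Hispanic 29, Other 28 — so the configured Black−White difference of −6
  months is *exactly* the mean ground-truth estimand, not an
  approximation through slope space. Curvature is mild
  (0.3 ± 0.05 eGFR/yr², clamped ≥ 0); the linear coefficient follows from
  (D, curvature).
* **Observation.** Visits run roughly every 6 months (0.5 ± 0.05 yr) over
  the ~3 years preceding KRT (lead-in 3 ± 0.5 yr), the supplemental
  collection window of the emulated study; the first visit is capped so
  entry eGFR stays below 90. KRT occurs just after the true crossing of
  the KRT threshold (10 + optional race offset), except that
  preemptive-transplant subjects stop 0–0.8 yr *before* the 10-crossing.
* **Observables.** Creatinine — not eGFR — is the generated quantity:
  true eGFR is pushed through the closed-form inverse of the
  clinical-practice equations (including the age-18 switch) and
  multiplied by lognormal noise at CV 5%, so the equation layer is
  genuinely exercised on the way back. Height follows a deliberately
  simple piecewise-linear growth curve with a sex offset (documented as
  non-anthropometric). Urine measures are missing 15% of the time and
  otherwise emitted as ACR, PCR, or dipstick-only (50/25/25), with ACR
  lognormal by CKD cause (glomerular markedly higher).
* **Outcomes.** Each outcome flag is drawn from its configured logistic
  model in the *true* years with low eGFR: log-OR 1.45/yr for preemptive
  transplant, 1.42/yr for living-donor transplant, 0 for preemptive
  waitlisting, with intercepts set to the emulated cohort's prevalences
  (45%, 27%, 77%). Profile fields (KRT modality, waitlist status, donor
  type) are reconciled with the flags so invariants hold (donor type
  present only for transplant recipients).
* **Violators.** 5% of subjects per filter are deliberately constructed
  to fail each eligibility criterion (2 visits only; declining but never
  below 30; rising eGFR), so the filter layer is testable; all other
  subjects satisfy eligibility by construction.

What the generator does **not** emulate: informative visit-frequency
processes, realistic growth references, death before KRT, site effects,
measurement-batch effects, and any dependence of outcomes on race beyond
what flows through the true duration. Passing parameter-recovery tests
therefore demonstrates internal statistical validity of the pipeline — it
does not validate the equations or models against real patients.

`make_table4_fixture()` is a separate 333-row deterministic table
reproducing published marginal counts for the descriptive-report layer;
its joint category assignment is invented and carries no information.

## Numerical and reporting choices

* Crossing-time roots: linear fallback when |c| < 1e−12; tangent
  (zero-slope) contacts do not count as crossings.
* Percentages print as nearest integer with ties away from zero; every
  printed percentage re-derives from its counts (audited in tests).
  Group tests: chi-square for categorical blocks, Kruskal–Wallis for
  continuous; single-group tables suppress p-values with a note.
* Determinism: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); a (config, seed) pair reproduces pipeline
  outputs byte-for-byte, recorded as content hashes in the run manifest.
* Problem sizes: parameter-recovery checks use 100 cohorts of n=300
  (duration contrast) and replicated n=2000 cohorts (outcome log-OR);
  null calibration uses 200–400 cohorts; these sizes give Monte Carlo
  error comfortably below the tolerances they are checked against.

## Known limitations

Conversion coefficients for dipstick/ACR/PCR are placeholders (above).
The mixed model assumes homoscedastic residuals while multiplicative
creatinine noise implies slightly eGFR-proportional errors — at CV 5%
this is negligible for the contrasts studied. BLUP shrinkage attenuates
between-group duration differences very mildly when between-subject slope
variance is small relative to residual noise; under realistic
heterogeneity the recovery bias measured in the acceptance checks is well
under a month. Visit stopping tied to the KRT threshold induces no
selection under the default design, but custom configurations with very
short lead-ins can reintroduce it.
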