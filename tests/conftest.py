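import pytest

import ckdtime as ck


@pytest.fixture(scope="session")
def constants():
    return ck.load_constants()


@pytest.fixture(scope="session")
def conversion_model():
    return ck.load_conversion_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = ck.GeneratorConfig(n_subjects=120)
    return ck.generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def eligible_cohort(small_cohort):
    visits, subjects, truth = small_cohort
    v, s, log = ck.apply_eligibility(visits, subjects)
    return v, s, truth, log


@pytest.fixture(scope="session")
def fitted_scheme(eligible_cohort):
    """Schwartz/CKD-EPI eGFR table + mixed-model fit for the shared cohort."""
    v, s, truth, _ = eligible_cohort
    table, skipped = ck.compute_egfr_table(v, s, "schwartz_ckdepi")
    origin = table.groupby("subject_id")["visit_time"].transform("min")
    fit = ck.fit_trajectory_lmm(table.assign(time=table["visit_time"] - origin),
                                scheme="schwartz_ckdepi")
    return table, fit
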