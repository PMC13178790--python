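"""Synthetic cohort generator: determinism, ground-truth consistency,
configured margins, and the printed-counts fixture."""

import numpy as np
import pandas as pd
import pytest

import ckdtime as ck


def test_generator_deterministic_for_fixed_seed():
    cfg = ck.GeneratorConfig(n_subjects=60)
    a = ck.generate_cohort(cfg, seed=3)
    b = ck.generate_cohort(cfg, seed=3)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
    c = ck.generate_cohort(cfg, seed=4)
    assert not a[0].equals(c[0])


def test_noiseless_creatinine_reproduces_true_egfr(small_cohort):
    cfg = ck.GeneratorConfig(n_subjects=40, scr_noise_cv=0.0)
    visits, subjects, truth = ck.generate_cohort(cfg, seed=8)
    table, _ = ck.compute_egfr_table(visits, subjects, "schwartz_ckdepi")
    coef = truth.set_index("subject_id")
    for row in table.itertuples(index=False):
        tr = coef.loc[row.subject_id]
        expected = tr.a + tr.b * row.visit_time + tr.c * row.visit_time**2
        assert row.egfr == pytest.approx(expected, rel=1e-9)


def test_zero_noise_pipeline_recovers_true_durations():
    cfg = ck.GeneratorConfig(
        n_subjects=60, scr_noise_cv=0.0, curvature_mean=0.0, curvature_sd=0.0,
        violator_fracs={"few_visits": 0, "no_low_egfr": 0, "non_decline": 0},
    )
    visits, subjects, truth = ck.generate_cohort(cfg, seed=12)
    v, s, _ = ck.apply_eligibility(visits, subjects)
    table, _sk = ck.compute_egfr_table(v, s, "schwartz_ckdepi")
    origin = table.groupby("subject_id")["visit_time"].transform("min")
    fit = ck.fit_trajectory_lmm(table.assign(time=table["visit_time"] - origin))
    summ = ck.derive_crossing_summaries(fit, s).set_index("subject_id")
    tr = truth.set_index("subject_id")
    for sid in summ.index:
        assert summ.loc[sid, "low_egfr_months"] == pytest.approx(
            tr.loc[sid, "true_low_egfr_months"], abs=0.5
        )


def test_race_shares_match_configured_probabilities():
    cfg = ck.GeneratorConfig(n_subjects=5000)
    _, subjects, _ = ck.generate_cohort(cfg, seed=77)
    shares = subjects["race_ethnicity"].value_counts(normalize=True)
    for race, p in cfg.race_probs.items():
        assert shares[race] == pytest.approx(p, abs=0.02)


def test_ground_truth_duration_consistent_with_coefficients(small_cohort):
    _, _, truth = small_cohort
    reg = truth[truth["violator_type"] == ""]
    for row in reg.itertuples(index=False):
        t30 = ck.crossing_time((row.a, row.b, row.c), 30.0, t_min=-30.0)
        t10 = ck.crossing_time((row.a, row.b, row.c), 10.0, t_min=-30.0)
        assert 12 * (t10 - t30) == pytest.approx(row.true_low_egfr_months, abs=1e-6)
        assert row.t10_true > row.t30_true


def test_mean_true_duration_contrast_matches_config():
    cfg = ck.GeneratorConfig(n_subjects=6000)
    _, subjects, truth = ck.generate_cohort(cfg, seed=13)
    df = truth[truth["violator_type"] == ""].merge(
        subjects[["subject_id", "race_ethnicity"]], on="subject_id"
    )
    means = df.groupby("race_ethnicity")["true_low_egfr_months"].mean()
    assert means["White"] == pytest.approx(30.0, abs=0.8)
    assert means["Black"] == pytest.approx(24.0, abs=0.8)


def test_outcome_flags_follow_configured_logistic_model():
    cfg = ck.GeneratorConfig(n_subjects=2000)
    _, _, truth = ck.generate_cohort(cfg, seed=29)
    df = truth[truth["violator_type"] == ""].copy()
    df["exposure_years"] = df["true_low_egfr_months"] / 12.0
    df = df.rename(columns={"y_preemptive_transplant": "pt"})
    eff = ck.fit_outcome_logistic(df, "pt", adjustment_set="none")
    assert np.log(eff.or_per_year) == pytest.approx(np.log(1.45), abs=0.2)


def test_invalid_generator_configs_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        ck.GeneratorConfig(race_probs={"White": 0.5, "Black": 0.2})
    with pytest.raises(ValueError, match="exceed the gamma shift"):
        ck.GeneratorConfig(duration_mean_months_by_race={
            "White": 5.0, "Black": 5.0, "Hispanic": 5.0, "Other": 5.0})
    with pytest.raises(ValueError, match="visit_interval"):
        ck.GeneratorConfig(visit_interval=0.0)


def test_table4_fixture_reproduces_printed_counts():
    fx = ck.make_table4_fixture()
    assert len(fx) == 333
    assert (fx["krt_modality"] == "preemptive_transplant").sum() == 149
    assert (fx["donor_type"] == "living").sum() == 89
    race_counts = fx["race_ethnicity"].value_counts()
    assert race_counts.to_dict() == {"White": 160, "Black": 72, "Hispanic": 65, "Other": 36}
    assert (fx["waitlist_status"] == "preemptive").sum() == 256
    assert (fx["ckd_cause"] == "glomerular").sum() == 75
    # donor type present exactly on transplanted rows
    tx = fx[fx["donor_type"] != ""]
    assert (tx["krt_modality"] == "preemptive_transplant").all()
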