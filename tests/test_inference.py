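"""Bootstrap scheme contrasts, outcome logistics, interaction tests."""

import numpy as np
import pandas as pd
import pytest

import ckdtime as ck


def _outcome_df(n=400, logor=0.0, intercept=-0.5, seed=0, races=None):
    rng = np.random.default_rng(seed)
    years = rng.gamma(6.0, 0.4, n)
    p = 1 / (1 + np.exp(-(intercept + logor * years)))
    df = pd.DataFrame({
        "exposure_years": years,
        "event": (rng.random(n) < p).astype(int),
        "age_at_entry": rng.uniform(3, 19, n),
        "sex": rng.choice(["female", "male"], n),
        "ckd_cause": rng.choice(["glomerular", "CAKUT", "other_unknown"], n),
        "race_ethnicity": rng.choice(races or ["White", "Black", "Hispanic", "Other"], n),
        "log_acr": rng.normal(3, 1.5, n),
    })
    return df


def test_closed_form_odds_ratio_on_2x2_table():
    # exposed: 8/10 events; unexposed: 2/10 -> OR = (8*8)/(2*2) = 16
    df = pd.DataFrame({
        "exposure_years": [1] * 10 + [0] * 10,
        "event": [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8,
    })
    eff = ck.fit_outcome_logistic(df, "event", adjustment_set="none")
    assert eff.or_per_year == pytest.approx(16.0, rel=1e-4)
    assert eff.ci_low <= eff.or_per_year <= eff.ci_high


def test_null_exposure_gives_near_unit_odds_ratio():
    eff = ck.fit_outcome_logistic(_outcome_df(n=2000, logor=0.0, seed=5), "event")
    assert 0.9 <= eff.or_per_year <= 1.1


def test_configured_log_or_recovered():
    df = _outcome_df(n=2000, logor=np.log(1.45), intercept=-1.0, seed=9)
    eff = ck.fit_outcome_logistic(df, "event")
    # 3x the asymptotic SE of the exposure coefficient at this n
    assert np.log(eff.or_per_year) == pytest.approx(np.log(1.45), abs=0.2)


def test_or_invariant_to_exposure_recentering():
    df = _outcome_df(n=800, logor=0.3, seed=2)
    a = ck.fit_outcome_logistic(df, "event")
    shifted = df.assign(exposure_years=df["exposure_years"] + 5.0)
    b = ck.fit_outcome_logistic(shifted, "event")
    assert a.or_per_year == pytest.approx(b.or_per_year, rel=1e-6)


def test_adjustment_tiers_and_complete_case_acr():
    df = _outcome_df(n=600, logor=0.3, seed=3)
    df.loc[df.index[:100], "log_acr"] = np.nan
    full = ck.fit_outcome_logistic(df, "event", adjustment_set="demographic+albuminuria")
    assert full.n_dropped_missing_acr == 100
    assert full.n_used == 500
    demo = ck.fit_outcome_logistic(df, "event", adjustment_set="demographic")
    assert demo.n_used == 600


def test_degenerate_outcome_is_an_error():
    df = _outcome_df(n=50, seed=1)
    df["event"] = 1
    with pytest.raises(ValueError, match="variation"):
        ck.fit_outcome_logistic(df, "event")


def test_perfect_separation_is_a_named_error():
    df = pd.DataFrame({
        "exposure_years": np.r_[np.zeros(20), np.ones(20)],
        "event": np.r_[np.zeros(20), np.ones(20)].astype(int),
    })
    with pytest.raises(ValueError):
        ck.fit_outcome_logistic(df, "event")


def test_interaction_single_race_group_is_an_error():
    df = _outcome_df(n=200, seed=4, races=["White"])
    with pytest.raises(ValueError, match="race groups"):
        ck.interaction_test(df, "event")


def test_interaction_null_p_not_degenerate():
    p = ck.interaction_test(_outcome_df(n=800, logor=0.3, seed=6), "event")
    assert 0.0 < p <= 1.0


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = ck.GeneratorConfig(
        n_subjects=70,
        violator_fracs={"few_visits": 0, "no_low_egfr": 0, "non_decline": 0},
    )
    visits, subjects, _ = ck.generate_cohort(cfg, seed=21)
    v, s, _ = ck.apply_eligibility(visits, subjects)
    return v, s


def test_bootstrap_identical_schemes_yields_zero_contrast(tiny_cohort):
    v, s = tiny_cohort
    contrasts = ck.bootstrap_equation_contrast(
        v, s, schemes=("u25", "u25"), n_reps=8, seed=5
    )
    for c in contrasts:
        assert c.delta_beta == 0.0
        assert c.ci_low == 0.0 and c.ci_high == 0.0
        assert np.all(c.per_rep_values == 0.0)


def test_bootstrap_deterministic_under_fixed_seed(tiny_cohort):
    v, s = tiny_cohort
    run = lambda: ck.bootstrap_equation_contrast(
        v, s, schemes=("schwartz_ckdepi", "u25"), n_reps=6, seed=17
    )
    first, second = run(), run()
    for a, b in zip(first, second):
        assert a.contrast_label == b.contrast_label
        assert a.delta_beta == b.delta_beta
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        np.testing.assert_array_equal(a.per_rep_values, b.per_rep_values)


def test_scheme_betas_cover_all_nonreference_groups(tiny_cohort):
    v, s = tiny_cohort
    betas = ck.scheme_race_betas(v, s, "schwartz_ckdepi")
    assert set(betas) <= {"Black vs White", "Hispanic vs White", "Other vs White"}
    assert len(betas) >= 2
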