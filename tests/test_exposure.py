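"""Threshold-crossing times, low-eGFR durations, race contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ckdtime as ck
from ckdtime.exposure import low_egfr_duration
from ckdtime.trajectory import TrajectoryFit


def grid_scan_crossing(coeffs, threshold, t_min=0.0, horizon=30.0, dt=1e-4):
    """Independent brute-force oracle: first sign change with negative slope."""
    a, b, c = coeffs
    t = np.arange(t_min, horizon, dt)
    y = a + b * t + c * t * t
    above = y > threshold
    for i in range(1, len(t)):
        if above[i - 1] and not above[i]:
            slope = b + 2 * c * t[i]
            if slope < 0:
                return t[i]
    return None


@pytest.mark.parametrize(
    "coeffs, threshold, expected",
    [
        ((30.0, -10.0, 0.0), 10.0, 2.0),  # linear closed form
        ((40.0, -12.0, 0.5), 10.0, 2.8349),  # smaller quadratic root
        ((30.0, 0.0, 0.0), 10.0, None),  # flat: never crosses
        ((10.0, 0.0, 0.0), 10.0, None),  # sits on the threshold, never crosses
        ((10.0, -1.0, 0.0), 10.0, 0.0),  # crossing exactly at the origin
    ],
)
def test_crossing_time_examples(coeffs, threshold, expected):
    got = ck.crossing_time(coeffs, threshold)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-4)


def test_crossing_time_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        ck.crossing_time((30, -10, 0), 0.0)


def test_crossing_time_agrees_with_grid_scan_oracle():
    rng = np.random.default_rng(11)
    n_checked = 0
    for _ in range(200):
        a = rng.uniform(20, 60)
        b = rng.uniform(-15, -2)
        c = rng.uniform(0, 0.6)
        got = ck.crossing_time((a, b, c), 10.0)
        ref = grid_scan_crossing((a, b, c), 10.0)
        if ref is None:
            assert got is None
            continue
        assert got == pytest.approx(ref, abs=1e-3)
        n_checked += 1
    assert n_checked > 100


def _fit_for(coeffs_by_subject):
    return TrajectoryFit(
        beta0=0.0, beta1=0.0, beta2=list(coeffs_by_subject.values())[0][2],
        random_effects={
            sid: (a, b) for sid, (a, b, _c) in coeffs_by_subject.items()
        },
        G=np.eye(2), sigma2=1.0,
    )


def test_linear_duration_closed_form():
    fit = _fit_for({"lin": (40.0, -5.0, 0.0)})
    summary = low_egfr_duration(fit, "lin")
    assert summary.t30 == pytest.approx(2.0)
    assert summary.t10 == pytest.approx(6.0)
    assert summary.low_egfr_months == pytest.approx(48.0)
    assert summary.crossing_status == "both"


@given(slope=st.floats(-30, -1.5))  # keeps the 10-crossing inside the horizon
@settings(max_examples=40, deadline=None)
def test_linear_duration_is_240_over_slope(slope):
    fit = _fit_for({"s": (45.0, slope, 0.0)})
    months = low_egfr_duration(fit, "s").low_egfr_months
    assert months == pytest.approx(12.0 * 20.0 / abs(slope), rel=1e-9)
    # steeper decline, strictly shorter duration
    steeper = low_egfr_duration(_fit_for({"s": (45.0, slope - 1.0, 0.0)}), "s")
    assert steeper.low_egfr_months < months


def test_krt_anchored_months_sign_convention():
    # modelled 10-crossing at ~2.835y; KRT observed at 3.0y -> positive gap
    fit = _fit_for({"q": (40.0, -12.0, 0.5)})
    s = low_egfr_duration(fit, "q", krt_date=3.0)
    assert s.months_t10_to_krt == pytest.approx(12 * (3.0 - 2.8349), abs=2e-3)
    # KRT before the modelled crossing flips the sign
    early = low_egfr_duration(fit, "q", krt_date=2.0)
    assert early.months_t10_to_krt < 0


def test_upward_curving_subject_flagged_only30():
    # vertex of 35 - 8t + 2t^2 is at eGFR 27: crosses 30 but never 10
    fit = _fit_for({"u": (35.0, -8.0, 2.0)})
    s = low_egfr_duration(fit, "u")
    assert s.crossing_status == "only30"
    assert s.low_egfr_months is None


def test_entry_below_30_gives_negative_t30():
    fit = _fit_for({"low": (25.0, -10.0, 0.0)})
    s = low_egfr_duration(fit, "low")
    assert s.t30 == pytest.approx(-0.5)
    assert s.low_egfr_months == pytest.approx(24.0)


def test_duration_invariant_to_time_origin_shift(eligible_cohort):
    v, s, _, _ = eligible_cohort
    def durations(visits):
        table, _sk = ck.compute_egfr_table(visits, s, "schwartz_ckdepi")
        origin = table.groupby("subject_id")["visit_time"].transform("min")
        fit = ck.fit_trajectory_lmm(table.assign(time=table["visit_time"] - origin))
        return ck.derive_crossing_summaries(fit, s).set_index("subject_id")["low_egfr_months"]
    base = durations(v)
    shifted = durations(v.assign(visit_time=v["visit_time"] + 2.0))
    pd.testing.assert_series_equal(base, shifted, atol=1e-6, rtol=0)


def _toy_summaries(durations_by_race):
    rows, profiles = [], []
    i = 0
    for race, values in durations_by_race.items():
        for d in values:
            rows.append({"subject_id": f"r{i}", "low_egfr_months": d})
            profiles.append({"subject_id": f"r{i}", "race_ethnicity": race})
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(profiles)


def test_race_ols_saturated_means_model():
    summaries, profiles = _toy_summaries({"White": [30.0, 30.0], "Black": [24.0, 24.0]})
    effects = ck.race_effect_regression(summaries, profiles)
    (eff,) = effects
    assert eff.contrast_label == "Black vs White"
    assert eff.beta_months == pytest.approx(-6.0, abs=1e-9)


def test_race_ols_null_when_groups_identical():
    summaries, profiles = _toy_summaries(
        {"White": [28.0, 28.0], "Black": [28.0, 28.0], "Hispanic": [28.0, 28.0]}
    )
    for eff in ck.race_effect_regression(summaries, profiles):
        assert eff.beta_months == pytest.approx(0.0, abs=1e-9)


def test_race_ols_requires_reference_group():
    summaries, profiles = _toy_summaries({"Black": [24.0, 25.0], "Hispanic": [26.0, 27.0]})
    with pytest.raises(ValueError, match="White"):
        ck.race_effect_regression(summaries, profiles)
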