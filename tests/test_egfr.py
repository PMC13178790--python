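"""eGFR estimating equations and age dispatch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ckdtime as ck
from ckdtime.egfr import VisitRecord


@pytest.mark.parametrize(
    "height, scr, expected",
    [
        (100.0, 0.413, 100.0),  # multiplier cancels exactly
        (140.0, 1.0, 57.82),
        (150.0, 2.0, 30.975),
    ],
)
def test_bedside_schwartz_values(height, scr, expected):
    assert ck.egfr_bedside_schwartz(height, scr) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "scr, age, sex, expected",
    [
        # frozen from direct evaluation of the published adult equation
        (0.9, 18.0, "male", 126.961),
        (4.0, 20.0, "male", 20.936),
        (0.7, 18.0, "female", 128.484),  # scr == kappa: only age/sex factors act
    ],
)
def test_ckdepi2021_values(scr, age, sex, expected):
    assert ck.egfr_ckdepi2021(scr, age, sex) == pytest.approx(expected, abs=5e-3)


def test_u25_uses_band_multiplier_at_exact_age(constants):
    # k(10, male) = 39.0 * 1.008**(10-12); eGFR = k * height(m) / scr
    k10 = 39.0 * 1.008 ** (-2)
    assert ck.egfr_u25(1.40, 1.0, 10.0, "male") == pytest.approx(k10 * 1.40, rel=1e-12)
    # within one band a half-year of age moves the output by factor^0.5
    r = ck.egfr_u25(1.40, 1.0, 10.5, "male") / ck.egfr_u25(1.40, 1.0, 10.0, "male")
    assert r == pytest.approx(1.008 ** 0.5, rel=1e-12)


def test_u25_doubling_scr_halves_output():
    one = ck.egfr_u25(1.40, 1.0, 7.3, "female")
    assert ck.egfr_u25(1.40, 2.0, 7.3, "female") == pytest.approx(one / 2, rel=1e-12)


@pytest.mark.parametrize(
    "age, scheme, matches",
    [
        (17.9, "schwartz_ckdepi", "schwartz"),  # strict < 18
        (18.0, "schwartz_ckdepi", "ckdepi"),  # inclusive on the adult side
        (18.0, "u25", "u25"),  # U25 covers the whole [1, 25) range
    ],
)
def test_dispatch_age_boundaries(age, scheme, matches):
    visit = VisitRecord("x", age=age, scr=2.0, visit_time=0.0, height=160.0)
    got = ck.egfr_dispatch(visit, "male", scheme)
    by_name = {
        "schwartz": ck.egfr_bedside_schwartz(160.0, 2.0),
        "ckdepi": ck.egfr_ckdepi2021(2.0, age, "male") if age >= 18 else None,
        "u25": ck.egfr_u25(1.60, 2.0, age, "male"),
    }
    assert got == pytest.approx(by_name[matches], rel=1e-12)
    if matches == "u25" and age >= 18:
        assert got != pytest.approx(by_name["ckdepi"], rel=1e-3)


@given(
    height=st.floats(60, 200),
    scr=st.floats(0.2, 12),
    scale=st.floats(1.1, 3.0),
)
@settings(max_examples=50, deadline=None)
def test_schwartz_proportionality(height, scr, scale):
    base = ck.egfr_bedside_schwartz(height, scr)
    assert ck.egfr_bedside_schwartz(height * scale, scr) == pytest.approx(base * scale, rel=1e-9)
    assert ck.egfr_bedside_schwartz(height, scr * scale) == pytest.approx(base / scale, rel=1e-9)
    assert base > 0


@given(scr=st.floats(0.3, 10), age=st.floats(18, 40), bump=st.floats(0.05, 2))
@settings(max_examples=50, deadline=None)
def test_ckdepi_monotone_decreasing(scr, age, bump):
    base = ck.egfr_ckdepi2021(scr, age, "female")
    assert ck.egfr_ckdepi2021(scr + bump, age, "female") < base
    assert ck.egfr_ckdepi2021(scr, age + bump, "female") < base
    assert base > 0


@pytest.mark.parametrize(
    "call, err",
    [
        (lambda: ck.egfr_bedside_schwartz(-5, 1.0), ck.InvalidInputError),
        (lambda: ck.egfr_bedside_schwartz(140, 0.0), ck.InvalidInputError),
        (lambda: ck.egfr_ckdepi2021(1.0, 17.0, "male"), ck.DispatchViolationError),
        (lambda: ck.egfr_u25(1.4, 1.0, 25.0, "male"), ck.DispatchViolationError),
        (lambda: ck.egfr_u25(1.4, 1.0, 0.5, "male"), ck.DispatchViolationError),
    ],
)
def test_invalid_inputs_raise(call, err):
    with pytest.raises(err):
        call()


def test_error_names_offending_field():
    with pytest.raises(ck.InvalidInputError, match="height"):
        ck.egfr_bedside_schwartz(0, 1.0)
    with pytest.raises(ck.InvalidInputError, match="scr"):
        ck.egfr_bedside_schwartz(140, -1.0)


def test_dispatch_totality_counts_reconcile():
    visits = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b"],
            "visit_time": [0.0, 0.5, 0.0, 0.5],
            "age": [10.0, 10.5, 26.0, 26.5],  # b is outside the U25 range
            "height": [140.0, None, 170.0, 170.0],  # a's 2nd visit lacks height
            "scr": [1.0, 1.1, 2.0, 2.1],
        }
    )
    subjects = pd.DataFrame({"subject_id": ["a", "b"], "sex": ["male", "female"]})
    table, skipped = ck.compute_egfr_table(visits, subjects, "u25")
    assert len(visits) == len(table) + len(skipped)
    assert len(skipped) == 3  # missing height + two over-age visits
    assert (table["egfr"] > 0).all()


@given(
    egfr=st.floats(5, 120),
    age=st.floats(2, 24),
    scheme=st.sampled_from(["schwartz_ckdepi", "u25"]),
)
@settings(max_examples=60, deadline=None)
def test_inverse_roundtrip(egfr, age, scheme):
    height = 100.0 + 3 * age
    scr = ck.invert_scheme_scr(egfr, age, "female", height, scheme)
    visit = VisitRecord("x", age=age, scr=scr, visit_time=0.0, height=height)
    assert ck.egfr_dispatch(visit, "female", scheme) == pytest.approx(egfr, rel=1e-9)
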