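from datetime import date

import numpy as np
import pandas as pd
import pytest

from rxits.cohort import (
    CohortConfig,
    build_cessation_series,
    build_initiation_series,
    build_risk_score_series,
    classify_prevention,
    compute_episode_end,
    episodes_from_prescriptions,
    stratify_cessation,
)
from tests.conftest import make_tables, patient

CFG = CohortConfig()


# ----------------------------------------------------------------------
# episode ends
# ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "start, quantity, dose, fallback, expected",
    [
        (date(2013, 1, 1), 28, 1.0, None, date(2013, 1, 29)),
        (date(2013, 1, 1), 56, 2.0, None, date(2013, 1, 29)),
        (date(2013, 1, 1), 30, None, 1.0, date(2013, 1, 31)),
        (date(2013, 1, 1), 29, 2.0, None, date(2013, 1, 16)),  # ceil(29/2)=15
    ],
)
def test_episode_end_is_start_plus_supply_days(start, quantity, dose, fallback, expected):
    assert compute_episode_end(start, quantity, dose, fallback) == expected


def test_episode_end_requires_some_dose():
    with pytest.raises(ValueError, match="dose"):
        compute_episode_end(date(2013, 1, 1), 28, None, None)


def test_missing_dose_falls_back_to_per_drug_median():
    rx = pd.DataFrame(
        {
            "patient_id": [1, 1, 1],
            "drug_code": ["s"] * 3,
            "issue_date": pd.to_datetime(["2012-01-01", "2012-02-01", "2012-03-01"]),
            "quantity": [56, 56, 56],
            "daily_dose": [2.0, 2.0, np.nan],
        }
    )
    ep = episodes_from_prescriptions(rx)
    assert len(ep) == 3
    # median dose 2/day -> 28-day supply
    assert (ep["end_date"] - ep["start_date"]).dt.days.tolist() == [28, 28, 28]


# ----------------------------------------------------------------------
# prevention classification
# ----------------------------------------------------------------------


def test_prevention_is_secondary_only_for_strictly_prior_events():
    tab = make_tables(
        [patient(1), patient(2), patient(3)],
        events=[(1, date(2012, 5, 1), "cv"), (3, date(2013, 1, 1), "cv")],
    )
    assert classify_prevention(1, date(2013, 1, 1), tab.events) == "secondary"
    assert classify_prevention(2, date(2013, 1, 1), tab.events) == "primary"
    # event on the reference date itself: strict inequality, still primary
    assert classify_prevention(3, date(2013, 1, 1), tab.events) == "primary"


# ----------------------------------------------------------------------
# initiation
# ----------------------------------------------------------------------


def _init_fixture(rx_day, death=None):
    rx = [(1, "statin_a", rx_day, 28, 1.0)] if rx_day else []
    return make_tables(
        [patient(1, death=death, end=death or date(2016, 1, 1))],
        prescriptions=rx,
        scores=[(1, date(2012, 3, 10), 25.0)],
    )


def test_initiation_within_grace_counts():
    s = build_initiation_series(_init_fixture(date(2012, 3, 20)), CFG, "primary")
    row = s.data[(s.data.year == 2012) & (s.data.month == 3)].iloc[0]
    assert (row.denominator, row.numerator) == (1, 1)


def test_initiation_on_day_28_counts_but_day_30_does_not():
    on28 = build_initiation_series(_init_fixture(date(2012, 4, 7)), CFG, "primary")
    row = on28.data[(on28.data.year == 2012) & (on28.data.month == 3)].iloc[0]
    assert (row.denominator, row.numerator) == (1, 1)
    on30 = build_initiation_series(_init_fixture(date(2012, 4, 9)), CFG, "primary")
    row = on30.data[(on30.data.year == 2012) & (on30.data.month == 3)].iloc[0]
    assert (row.denominator, row.numerator) == (1, 0)


def test_death_inside_grace_window_removes_from_denominator():
    s = build_initiation_series(_init_fixture(None, death=date(2012, 3, 20)), CFG, "primary")
    row = s.data[(s.data.year == 2012) & (s.data.month == 3)].iloc[0]
    assert (row.denominator, row.numerator) == (0, 0)


def test_secondary_initiation_sixty_day_grace_inclusive():
    def fixture(rx_day):
        return make_tables(
            [patient(1)],
            prescriptions=[(1, "statin_a", rx_day, 28, 1.0)],
            events=[(1, date(2012, 6, 1), "cv")],
        )

    on60 = build_initiation_series(fixture(date(2012, 7, 31)), CFG, "secondary")
    row = on60.data[(on60.data.year == 2012) & (on60.data.month == 6)].iloc[0]
    assert (row.denominator, row.numerator) == (1, 1)
    on61 = build_initiation_series(fixture(date(2012, 8, 1)), CFG, "secondary")
    row = on61.data[(on61.data.year == 2012) & (on61.data.month == 6)].iloc[0]
    assert (row.denominator, row.numerator) == (1, 0)


def test_underage_patient_excluded_from_initiation():
    tab = make_tables(
        [patient(1, birth_year=1975)],  # age ~36-37 in 2012
        scores=[(1, date(2012, 3, 10), 25.0)],
    )
    s = build_initiation_series(tab, CFG, "primary")
    assert s.data["denominator"].sum() == 0


# ----------------------------------------------------------------------
# cessation
# ----------------------------------------------------------------------


def _cess_fixture(next_issue=None, event=None, death=None):
    rx = [(1, "statin_a", date(2012, 5, 13), 28, 1.0)]  # ends 2012-06-10
    if next_issue:
        rx.append((1, "statin_a", next_issue, 28, 1.0))
    return make_tables(
        [patient(1, death=death, end=death or date(2016, 1, 1))],
        prescriptions=rx,
        events=[(1, event, "cv")] if event else [],
    )


def _june_row(series):
    return series.data[(series.data.year == 2012) & (series.data.month == 6)].iloc[0]


@pytest.mark.parametrize(
    "next_issue, ceased",
    [
        (date(2012, 7, 7), 0),  # day 27: continuation
        (date(2012, 7, 8), 0),  # day 28: continuation (inclusive boundary)
        (date(2012, 7, 9), 1),  # day 29: cessation
        (None, 1),
    ],
)
def test_cessation_grace_boundary_is_sharp(next_issue, ceased):
    s = build_cessation_series(_cess_fixture(next_issue), CFG, "primary")
    row = _june_row(s)
    assert row.denominator >= 1
    first = s.data[(s.data.year == 2012) & (s.data.month == 6)]
    assert first.iloc[0].numerator == ceased


def test_event_inside_grace_window_excludes_primary_episode():
    s = build_cessation_series(_cess_fixture(event=date(2012, 6, 20)), CFG, "primary")
    assert _june_row(s).denominator == 0


def test_event_on_end_date_excludes_primary_episode():
    s = build_cessation_series(_cess_fixture(event=date(2012, 6, 10)), CFG, "primary")
    assert _june_row(s).denominator == 0


def test_prior_event_routes_episode_to_secondary_series():
    tab = _cess_fixture(event=date(2011, 1, 5))
    prim = build_cessation_series(tab, CFG, "primary")
    sec = build_cessation_series(tab, CFG, "secondary")
    assert _june_row(prim).denominator == 0
    assert _june_row(sec).denominator == 1


def test_death_inside_grace_window_excludes_episode():
    s = build_cessation_series(_cess_fixture(death=date(2012, 6, 20)), CFG, "primary")
    assert _june_row(s).denominator == 0


def test_translation_by_a_year_shifts_series_by_12_months():
    tab = _cess_fixture(next_issue=date(2012, 7, 9))
    shifted = make_tables(
        [patient(1)],
        prescriptions=[
            (1, "statin_a", date(2013, 5, 13), 28, 1.0),
            (1, "statin_a", date(2013, 7, 9), 28, 1.0),
        ],
    )
    a = build_cessation_series(tab, CFG, "primary")
    b = build_cessation_series(shifted, CFG, "primary")
    ia = a.data.reset_index().set_index(["year", "month"])
    for (y, m), row in ia.iterrows():
        if (y + 1, m) in b.data.set_index(["year", "month"]).index:
            brow = b.data.set_index(["year", "month"]).loc[(y + 1, m)]
            if row.denominator or brow.denominator:
                assert (row.denominator, row.numerator) == (
                    brow.denominator,
                    brow.numerator,
                )


# ----------------------------------------------------------------------
# stratification
# ----------------------------------------------------------------------


def test_duration_chain_spans_bridged_gaps():
    """Three 28-day supplies with 10-day gaps form one 104-day chain,
    landing in the shortest duration category."""
    issues = [date(2012, 5, 1), date(2012, 6, 8), date(2012, 7, 16)]
    tab = make_tables(
        [patient(1, reg=date(2005, 1, 1))],
        prescriptions=[(1, "statin_a", d, 28, 1.0) for d in issues],
    )
    s = stratify_cessation(tab, CFG, "duration")
    last = s.data[(s.data.year == 2012) & (s.data.month == 8) & (s.data.denominator > 0)]
    assert last["stratum"].tolist() == ["le6m"]
    # chain: 2012-05-01 .. 2012-08-13 end = 104 days
    assert (date(2012, 8, 13) - date(2012, 5, 1)).days == 104


def test_duration_requires_chain_start_a_year_after_registration():
    tab = make_tables(
        [patient(1, reg=date(2011, 11, 1))],  # chain starts 200 days later
        prescriptions=[(1, "statin_a", date(2012, 5, 19), 28, 1.0)],
    )
    s = build_cessation_series(tab, CFG, "primary")
    assert s.data["denominator"].sum() == 1
    with pytest.raises(ValueError, match="strata"):
        stratify_cessation(tab, CFG, "duration")  # nothing left to stratify


def test_diabetes_stratum_is_time_anchored():
    tab = make_tables(
        [patient(1, diabetes=date(2013, 1, 1))],
        prescriptions=[(1, "statin_a", date(2012, 5, 13), 28, 1.0)],
    )
    s = stratify_cessation(tab, CFG, "diabetes")
    june = s.data[(s.data.year == 2012) & (s.data.month == 6) & (s.data.denominator > 0)]
    assert june["stratum"].tolist() == ["no_diabetes"]


def test_unknown_modifier_rejected(sim_tables):
    with pytest.raises(ValueError, match="modifier"):
        stratify_cessation(sim_tables, CFG, "bmi")


@pytest.mark.parametrize("modifier", ["age_group", "sex", "diabetes"])
def test_stratified_series_sum_to_unstratified(sim_tables, modifier):
    strat = stratify_cessation(sim_tables, CFG, modifier)
    total = build_cessation_series(sim_tables, CFG, "primary")
    agg = strat.totals()
    pd.testing.assert_frame_equal(
        agg.data[["year", "month", "denominator", "numerator"]],
        total.data[["year", "month", "denominator", "numerator"]],
    )


# ----------------------------------------------------------------------
# risk-score series
# ----------------------------------------------------------------------


def test_risk_category_boundaries():
    tab = make_tables(
        [patient(i) for i in range(1, 5)],
        scores=[
            (1, date(2012, 3, 5), 20.0),  # closed-left: 20-30 band
            (2, date(2012, 3, 6), 9.9),
            (3, date(2012, 3, 7), 30.0),
            (4, date(2012, 3, 8), 10.0),
        ],
    )
    march = lambda s: s.data[(s.data.year == 2012) & (s.data.month == 3)].iloc[0]
    assert march(build_risk_score_series(tab, CFG, "20to30")).numerator == 1
    assert march(build_risk_score_series(tab, CFG, "lt10")).numerator == 1
    assert march(build_risk_score_series(tab, CFG, "ge30")).numerator == 1
    assert march(build_risk_score_series(tab, CFG, "10to20")).numerator == 1
    assert march(build_risk_score_series(tab, CFG, "any")).numerator == 4
    assert march(build_risk_score_series(tab, CFG, "any")).denominator == 4
    # months without scores have numerator zero
    s = build_risk_score_series(tab, CFG, "any")
    assert s.data[(s.data.year == 2012) & (s.data.month == 5)].iloc[0].numerator == 0
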