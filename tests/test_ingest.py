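"""Cleaning rules, welfare-day filters and hourly aggregation."""

import numpy as np
import pandas as pd
import pytest

from circafeed.ingest import (
    CleaningRules,
    WelfareEvents,
    aggregate_hourly,
    clean_visits,
    filter_pig_days,
    parse_visits,
)
from circafeed.synth import (
    CohortSpec,
    ErrorInjectionSpec,
    alternans_profile,
    generate_hourly,
    generate_visits,
    inject_errors,
)


def _visit(pig, day, hour, minute, intake, dur_s=300, pen="p1"):
    e = pd.Timestamp("2021-01-01") + pd.Timedelta(days=day, hours=hour, minutes=minute)
    return {
        "pig_id": pig, "pen_id": pen, "entry_ts": e,
        "exit_ts": e + pd.Timedelta(seconds=dur_s), "intake_g": intake,
    }


def test_negative_intake_removed_and_reported():
    df = pd.DataFrame([_visit("a", 0, 10, 0, -12.0)])
    kept, report = clean_visits(df)
    assert len(kept) == 0
    assert report.n_removed_by_rule["neg_intake"] == 1
    assert report.n_visits_in == 1


def test_all_rules_disabled_is_identity():
    df = pd.DataFrame(
        [_visit("a", 0, 10, 0, -12.0), _visit("a", 0, 11, 0, 5000.0, dur_s=1)]
    )
    rules = CleaningRules(
        enable_neg_intake=False, enable_rate_max=False, enable_duration=False,
        enable_overlap=False, enable_bad_day=False,
    )
    kept, report = clean_visits(df, rules)
    assert len(kept) == len(df)
    assert report.n_visits_removed == 0


def test_exactly_injected_violations_removed():
    """Toy table with one violation per rule family: exactly the labelled
    records are removed; everything else survives and conserves mass."""
    good = [_visit("a", 0, h, 5, 80.0) for h in range(8, 18)]
    good += [_visit("b", 0, h, 10, 60.0) for h in range(8, 18)]
    df = pd.DataFrame(good)
    bad = pd.DataFrame(
        [
            _visit("a", 1, 9, 0, -30.0),                 # negative intake
            _visit("b", 1, 10, 0, 4000.0, dur_s=60),     # 4000 g/min rate
            _visit("a", 1, 11, 0, 90.0, dur_s=7200),     # 2 h visit
        ]
    )
    mixed = pd.concat([df, bad], ignore_index=True)
    kept, report = clean_visits(mixed, CleaningRules(day_frac_max=0.5))
    assert len(kept) == len(df)
    assert report.n_removed_by_rule["neg_intake"] == 1
    assert report.n_removed_by_rule["rate_max"] == 1
    assert report.n_removed_by_rule["duration"] == 1
    assert kept["intake_g"].sum() == df["intake_g"].sum()


def test_synthetic_corruption_caught_by_rules():
    spec = CohortSpec(n_pens=1, pigs_per_pen=2, n_days=10, missing_day_prob=0.0, seed=3)
    s = generate_hourly(alternans_profile(1.0), spec)
    visits = generate_visits(s, spec)
    corrupted, labels = inject_errors(
        visits, ErrorInjectionSpec(0.03, 0.03, 0.03, seed=5)
    )
    kept, report = clean_visits(corrupted, CleaningRules(enable_bad_day=False))
    # every corrupted record must be removed; clean ones survive
    n_corrupt = int((labels != "clean").sum())
    assert report.n_visits_removed == n_corrupt
    assert len(kept) == int((labels == "clean").sum())


def test_overlap_rule_removes_second_visit():
    v1 = _visit("a", 0, 10, 0, 50.0, dur_s=600)
    v2 = _visit("a", 0, 10, 5, 40.0, dur_s=60)  # starts inside v1
    kept, report = clean_visits(
        pd.DataFrame([v1, v2]), CleaningRules(enable_bad_day=False)
    )
    assert report.n_removed_by_rule["overlap"] == 1
    assert len(kept) == 1


def test_enabling_rules_never_increases_survivors():
    spec = CohortSpec(n_pens=1, pigs_per_pen=2, n_days=10, missing_day_prob=0.0, seed=4)
    s = generate_hourly(alternans_profile(0.7), spec)
    visits, _ = inject_errors(
        generate_visits(s, spec), ErrorInjectionSpec(0.05, 0.05, 0.05, seed=6)
    )
    base = CleaningRules(
        enable_neg_intake=False, enable_rate_max=False, enable_duration=False,
        enable_overlap=False, enable_bad_day=False,
    )
    n_prev = len(clean_visits(visits, base)[0])
    for flags in (
        {"enable_neg_intake": True},
        {"enable_neg_intake": True, "enable_rate_max": True},
        {"enable_neg_intake": True, "enable_rate_max": True, "enable_duration": True},
    ):
        kept, _ = clean_visits(visits, CleaningRules(**{**base.__dict__, **flags}))
        assert len(kept) <= n_prev
        n_prev = len(kept)


def test_unparseable_rows_quarantined():
    df = pd.DataFrame(
        [
            _visit("a", 0, 10, 0, 50.0),
            {"pig_id": "a", "pen_id": "p1", "entry_ts": "junk",
             "exit_ts": "junk", "intake_g": "x"},
        ]
    )
    parsed, n_quar = parse_visits(df)
    assert len(parsed) == 1
    assert n_quar == 1


# --- welfare-day filters ----------------------------------------------------

def _series(pig="a", n_days=60):
    vals = np.full((n_days, 24), 10.0)
    return __import__("circafeed.series", fromlist=["HourlyIntakeSeries"]).HourlyIntakeSeries(
        pig_id=pig, pen_id="p1", values=vals,
        missing_mask=np.zeros((n_days, 24), bool),
        day_index=np.arange(1, n_days + 1),
    )


def test_disease_day_masks_plus_minus_three_days():
    s = _series()
    ev = WelfareEvents(disease_days={"a": [30]})
    out, n = filter_pig_days(s, ev)
    masked_days = out.day_index[out.missing_mask.all(axis=1)]
    assert list(masked_days) == [27, 28, 29, 30, 31, 32, 33]
    assert n == 7


def test_empty_events_leave_series_unchanged():
    s = _series()
    ev = WelfareEvents(first_obs_day=1, slaughter_day=60)
    out, n = filter_pig_days(s, ev)
    assert n == 0
    np.testing.assert_array_equal(out.values, s.values)


def test_filter_removed_set_matches_enumeration():
    s = _series(n_days=80)
    ev = WelfareEvents(
        disease_days={"a": [10, 50]}, first_obs_day=5, slaughter_day=70
    )
    out, _ = filter_pig_days(s, ev)
    expected = set(range(1, 5)) | set(range(7, 14)) | set(range(47, 54)) | set(range(71, 81))
    got = set(out.day_index[out.missing_mask.all(axis=1)].tolist())
    assert got == expected


def test_filter_is_idempotent():
    s = _series()
    ev = WelfareEvents(disease_days={"a": [20]}, first_obs_day=3)
    once, _ = filter_pig_days(s, ev)
    twice, n2 = filter_pig_days(once, ev)
    assert n2 == 0
    np.testing.assert_array_equal(once.missing_mask, twice.missing_mask)


# --- aggregation ------------------------------------------------------------

def test_visits_in_same_hour_sum():
    df = pd.DataFrame(
        [_visit("a", 0, 10, 15, 50.0), _visit("a", 0, 10, 40, 30.0)]
    )
    df["duration_s"] = 300.0
    (s,) = aggregate_hourly(df, "2021-01-01", 1)
    assert s.values[0, 10] == 80.0


def test_boundary_spanning_visit_split_by_time():
    e = pd.Timestamp("2021-01-01 10:45:00")
    df = pd.DataFrame(
        [{"pig_id": "a", "pen_id": "p", "entry_ts": e,
          "exit_ts": e + pd.Timedelta(minutes=30), "intake_g": 60.0}]
    )
    (s,) = aggregate_hourly(df, "2021-01-01", 1)
    assert s.values[0, 10] == pytest.approx(30.0)
    assert s.values[0, 11] == pytest.approx(30.0)


def test_retained_day_without_visits_is_zero_not_missing():
    df = pd.DataFrame([_visit("a", 0, 10, 0, 50.0)])
    (s,) = aggregate_hourly(df, "2021-01-01", 2)
    assert s.values[1].sum() == 0
    assert not s.missing_mask[1].any()


def test_mass_conservation_through_cleaning_and_aggregation():
    spec = CohortSpec(n_pens=1, pigs_per_pen=1, n_days=14, missing_day_prob=0.0, seed=8)
    s = generate_hourly(alternans_profile(0.9), spec)
    visits = generate_visits(s, spec)
    kept, report = clean_visits(visits)
    (agg,) = aggregate_hourly(
        kept, spec.start_date, spec.n_days, removed_pig_days=report.removed_pig_days
    )
    assert agg.total_intake() == pytest.approx(kept["intake_g"].sum())
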