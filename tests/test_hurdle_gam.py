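"""Hurdle GAM: period assignment, fitting, recovery, LR comparisons."""

import numpy as np
import pytest

from circafeed.hurdle_gam import (
    assign_periods,
    fit_hurdle,
    lr_compare,
    period_availability,
    series_to_model_frame,
)
from circafeed.series import HourlyIntakeSeries
from circafeed.synth import (
    CohortSpec,
    DiurnalProfile,
    alternans_profile,
    generate_hourly,
)


def test_period_blocks_match_study_layout():
    """An 83-day window starting at day 5 yields five 14-day periods and
    one short final period."""
    p = assign_periods(5, 83, 14)
    assert list(p["day_start"]) == [5, 19, 33, 47, 61, 75]
    assert list(p["day_end"]) == [18, 32, 46, 60, 74, 83]
    assert list(p["n_days"])[:5] == [14] * 5
    assert p["n_days"].iloc[-1] == 9


def test_period_excluded_below_seven_days():
    spec = CohortSpec(n_days=28, missing_day_prob=0.0, seed=1)
    s = generate_hourly(alternans_profile(), spec)
    s.missing_mask[0:9, :] = True  # 9 of 14 days gone in period 1
    s.values[0:9, :] = np.nan
    periods = assign_periods(1, 28)
    avail = period_availability(s, periods)
    assert not avail.loc[avail["period_id"] == 1, "included"].iloc[0]
    assert avail.loc[avail["period_id"] == 2, "included"].iloc[0]


def test_availability_matches_enumeration_with_random_missingness():
    spec = CohortSpec(n_days=42, missing_day_prob=0.3, seed=17)
    s = generate_hourly(alternans_profile(), spec)
    periods = assign_periods(1, 42)
    avail = period_availability(s, periods)
    day_ok = ~s.missing_mask.all(axis=1)
    for _, row in periods.iterrows():
        sel = (s.day_index >= row["day_start"]) & (s.day_index <= row["day_end"])
        expected = int((day_ok & sel).sum())
        got = avail.loc[avail["period_id"] == row["period_id"], "n_available_days"].iloc[0]
        assert got == expected


def test_always_eating_pig_probability_near_one():
    prof = DiurnalProfile("flat", np.ones(24), np.full(24, 100.0), 1.0)
    spec = CohortSpec(n_days=14, missing_day_prob=0.0, sigma_pig=0, sigma_pen=0, seed=2)
    s = generate_hourly(prof, spec)
    fit = fit_hurdle(s, assign_periods(1, 14))
    pred = fit.predict(1, np.arange(24) + 0.5, 7.0)
    assert np.all(pred["prob"] > 0.99)
    assert np.all(pred["mu"] > 0)


def test_prediction_identity_prob_times_mu():
    spec = CohortSpec(n_days=28, missing_day_prob=0.0, seed=3)
    s = generate_hourly(alternans_profile(0.9), spec)
    fit = fit_hurdle(s, assign_periods(1, 28))
    grid = np.arange(0, 24, 0.25)
    for per in fit.included_periods:
        pred = fit.predict(per, grid, float(s.day_index[per * 7]))
        prod = pred["prob"].to_numpy() * pred["mu"].to_numpy()
        np.testing.assert_array_equal(pred["predicted_intake"].to_numpy(), prod)


def test_parameter_recovery_on_known_profile():
    """Fitted diurnal curve tracks p_eat * mu * trend at bin midpoints."""
    prof = alternans_profile(consistency=1.0)
    ratios = []
    for seed in range(3):
        spec = CohortSpec(
            n_days=70, missing_day_prob=0.0, sigma_pig=0.0, sigma_pen=0.0, seed=seed
        )
        s = generate_hourly(prof, spec)
        fit = fit_hurdle(s, assign_periods(1, 70))
        hours = np.arange(24) + 0.5
        for per in fit.included_periods:
            days = np.arange((per - 1) * 14 + 1, per * 14 + 1)
            trend = spec.trend_factor(days).mean()
            truth = prof.p_eat * prof.mu_intake * trend
            pred = fit.predict_detrended(per, hours)["predicted_intake"].to_numpy()
            amp = truth.max() - truth.min()
            ratios.append(np.sqrt(np.mean((pred - truth) ** 2)) / amp)
    assert np.mean(ratios) < 0.10


def test_cyclic_continuity_at_midnight():
    spec = CohortSpec(n_days=28, missing_day_prob=0.0, seed=5)
    s = generate_hourly(alternans_profile(0.8), spec)
    fit = fit_hurdle(s, assign_periods(1, 28))
    eps = 1e-4
    for per in fit.included_periods:
        f0 = fit.predict_detrended(per, np.array([0.0, eps, 24 - eps]))
        vals = f0["predicted_intake"].to_numpy()
        # value and slope continuous across the midnight wrap
        assert vals[1] == pytest.approx(vals[0], rel=1e-3)
        assert vals[2] == pytest.approx(vals[0], rel=1e-3)


def test_loglik_nesting_monotonicity():
    spec = CohortSpec(n_days=42, missing_day_prob=0.0, seed=6)
    s = generate_hourly(alternans_profile(0.8), spec)
    periods = assign_periods(1, 42)
    full = fit_hurdle(s, periods, kind="full")
    single = fit_hurdle(s, periods, kind="single_diurnal")
    trend = fit_hurdle(s, periods, kind="trend_only")
    assert full.loglik >= single.loglik - 1e-6
    assert single.loglik >= trend.loglik - 1e-6


def test_lr_compare_requires_same_data_and_detects_structure():
    spec = CohortSpec(n_days=42, missing_day_prob=0.0, seed=8)
    s = generate_hourly(alternans_profile(0.9), spec)
    periods = assign_periods(1, 42)
    full = fit_hurdle(s, periods)
    trend = fit_hurdle(s, periods, kind="trend_only")
    res = lr_compare(full, trend)
    assert res.df == full.n_params - trend.n_params
    assert res.pvalue < 1e-6  # strong diurnal structure present

    other = generate_hourly(alternans_profile(0.9), CohortSpec(n_days=28, seed=9))
    other_fit = fit_hurdle(other, assign_periods(1, 28))
    with pytest.raises(ValueError):
        lr_compare(full, other_fit)


def test_model_frame_uses_bin_midpoints_and_drops_missing():
    spec = CohortSpec(n_days=14, missing_day_prob=0.0, seed=10)
    s = generate_hourly(alternans_profile(), spec)
    s.missing_mask[3, :] = True
    s.values[3, :] = np.nan
    frame = series_to_model_frame(s, assign_periods(1, 14))
    assert set(np.unique(frame["hour"] % 1.0)) == {0.5}
    assert 4 not in set(frame["day"])  # day index 4 (row 3) removed
    assert len(frame) == 13 * 24
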