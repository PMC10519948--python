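"""LOESS de-trending, 7-day amplitude correction, zero fill."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circafeed.detrend import (
    DetrendedSeries,
    amplitude_correct,
    loess_detrend,
    prepare_series,
    zero_fill,
)
from circafeed.series import HourlyIntakeSeries
from circafeed.synth import CohortSpec, alternans_profile, generate_hourly


def _series_from_flat(vals, missing=None):
    n_days = len(vals) // 24
    v = np.asarray(vals, float).reshape(n_days, 24)
    m = (
        np.asarray(missing, bool).reshape(n_days, 24)
        if missing is not None
        else np.zeros((n_days, 24), bool)
    )
    v = v.copy()
    v[m] = np.nan
    return HourlyIntakeSeries("t", "p", v, m, np.arange(1, n_days + 1))


def _reference_local_linear(x, y, x0, frac):
    """Brute-force tricube-weighted degree-1 local regression at x0."""
    n = len(x)
    k = int(np.ceil(frac * n))
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, 1) ** 3
    X = np.column_stack([np.ones_like(x), x - x0])
    W = np.diag(w)
    beta = np.linalg.lstsq(W @ X, W @ y, rcond=None)[0]
    return beta[0]


def test_constant_series_gives_zero_residuals():
    s = _series_from_flat(np.full(7 * 24, 5.0))
    det = loess_detrend(s)
    assert np.allclose(det.values[~det.fill_mask], 0.0, atol=1e-8)


def test_loess_matches_reference_implementation_on_linear_ramp():
    rng = np.random.default_rng(3)
    n = 7 * 24
    y = 100.0 + 0.05 * np.arange(n) + rng.normal(0, 1, n)
    s = _series_from_flat(y)
    det = loess_detrend(s, span=0.75)
    x = np.arange(n, dtype=float)
    for i in [30, 84, 120]:
        ref = _reference_local_linear(x, y, x[i], 0.75)
        # small bandwidth-convention differences allowed; noise sd is 1
        assert det.trend_fit[i] == pytest.approx(ref, abs=0.05)


def test_residual_weekly_means_near_zero_on_trended_synth():
    spec = CohortSpec(
        n_days=28, missing_day_prob=0.0, sigma_pig=0.0, sigma_pen=0.0, seed=21
    )
    s = generate_hourly(alternans_profile(1.0), spec)
    det = loess_detrend(s)
    weekly = det.values[~det.fill_mask].reshape(4, -1).mean(axis=1)
    scale = np.nanstd(det.values)
    assert np.all(np.abs(weekly) < 0.35 * scale)


def test_all_missing_series_fails():
    s = _series_from_flat(np.zeros(48), missing=np.ones(48))
    with pytest.raises(ValueError):
        loess_detrend(s)


def test_amplitude_correction_normalises_block_range():
    vals = np.concatenate([np.linspace(0, 200, 7 * 24), np.linspace(0, 400, 7 * 24)])
    det = DetrendedSeries(
        values=vals, fill_mask=np.zeros(len(vals), bool),
        trend_fit=np.zeros(len(vals)), n_days=14, day_index=np.arange(14),
    )
    out = amplitude_correct(det)
    b1, b2 = out.values[: 7 * 24], out.values[7 * 24 :]
    assert b1.max() - b1.min() == pytest.approx(1.0)
    assert b2.max() - b2.min() == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_block_range_one_and_scale_invariance(seed):
    """Property: every valid block has range 1, and the correction is
    invariant to global rescaling of the input."""
    rng = np.random.default_rng(seed)
    n_days = int(rng.integers(7, 22))
    vals = rng.normal(0, 50, n_days * 24)
    det = DetrendedSeries(
        values=vals, fill_mask=rng.random(n_days * 24) < 0.1,
        trend_fit=np.zeros(n_days * 24), n_days=n_days, day_index=np.arange(n_days),
    )
    out = amplitude_correct(det)
    block = 7 * 24
    for b in range(len(out.block_valid)):
        if not out.block_valid[b]:
            continue
        sl = slice(b * block, min((b + 1) * block, n_days * 24))
        seg = out.values[sl][~out.fill_mask[sl]]
        assert np.nanmax(seg) - np.nanmin(seg) == pytest.approx(1.0)
    scaled = amplitude_correct(
        DetrendedSeries(values=vals * 3.7, fill_mask=det.fill_mask,
                        trend_fit=det.trend_fit, n_days=n_days,
                        day_index=det.day_index)
    )
    obs = ~det.fill_mask
    np.testing.assert_allclose(scaled.values[obs], out.values[obs], rtol=1e-12)


def test_degenerate_block_passes_through_flagged():
    vals = np.zeros(7 * 24)
    det = DetrendedSeries(
        values=vals, fill_mask=np.zeros(len(vals), bool),
        trend_fit=np.zeros(len(vals)), n_days=7, day_index=np.arange(7),
    )
    out = amplitude_correct(det)
    assert not out.block_valid[0]
    np.testing.assert_array_equal(out.values, vals)


def test_zero_fill_counts_match_missing_bits():
    vals = np.full(48, np.nan)
    vals[:24] = 1.0
    mask = np.isnan(vals)
    det = DetrendedSeries(
        values=vals, fill_mask=mask, trend_fit=np.zeros(48),
        n_days=2, day_index=np.arange(2),
    )
    out = zero_fill(det)
    assert np.all(out.values[mask] == 0.0)
    assert out.fill_mask.sum() == mask.sum()
    # identity on a fully observed series
    full = zero_fill(
        DetrendedSeries(values=np.ones(48), fill_mask=np.zeros(48, bool),
                        trend_fit=np.zeros(48), n_days=2, day_index=np.arange(2))
    )
    assert np.all(full.values == 1.0)


def test_prepare_series_chains_all_stages():
    spec = CohortSpec(n_days=21, missing_day_prob=0.1, seed=13)
    s = generate_hourly(alternans_profile(0.8), spec)
    det = prepare_series(s)
    assert det.filled
    assert not np.isnan(det.values).any()
    assert det.fill_mask.sum() == s.missing_mask.sum()
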