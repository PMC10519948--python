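"""Stationarising hourly intake for wavelet analysis.

Wavelet significance testing assumes roughly constant mean and variance.
Growing animals eat ever more (rising trend) and concentrate intake in
fewer hours as they age (rising amplitude), so each series is (1) LOESS
de-trended on the hourly time axis, (2) amplitude-corrected by dividing
each 7-day block by its own de-trended range, and (3) zero-filled at
missing points, with a mask retained so downstream interpretation can be
suppressed there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .series import HourlyIntakeSeries

__all__ = ["DetrendedSeries", "loess_detrend", "amplitude_correct", "zero_fill", "prepare_series"]


@dataclass
class DetrendedSeries:
    """Flat hourly vector after one or more stationarising steps.

    values : de-trended (and possibly amplitude-corrected) hourly intake;
        NaN where missing until :func:`zero_fill` runs.
    fill_mask : True at points that were missing (zero-filled at the end).
    trend_fit : the LOESS fit in grams, NaN at missing points.
    block_valid : per 7-day block, False where the range guard tripped and
        the block passed through unscaled.
    """

    values: np.ndarray
    fill_mask: np.ndarray
    trend_fit: np.ndarray
    n_days: int
    day_index: np.ndarray
    block_valid: np.ndarray | None = None
    filled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.fill_mask = np.asarray(self.fill_mask, dtype=bool)
        if self.values.shape != self.fill_mask.shape:
            raise ValueError("values and fill_mask shapes differ")
        if len(self.values) != self.n_days * 24:
            raise ValueError("length must equal n_days * 24")


def loess_detrend(series: HourlyIntakeSeries, span: float = 0.75) -> DetrendedSeries:
    """Subtract a locally linear (tricube-weighted) fit of intake on time.

    The regression runs on the true hourly time index with missing points
    left as gaps; ``span`` is the fraction of points in each local
    neighbourhood.  Residuals are returned at observed points; missing
    points stay NaN at this stage.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    y = series.flat_values()
    miss = series.flat_missing()
    obs = ~miss
    if obs.sum() < 2:
        raise ValueError(f"series {series.pig_id}: fewer than 2 observed points")
    t = np.arange(len(y), dtype=float)
    fit_at_obs = lowess(
        y[obs], t[obs], frac=span, it=0, return_sorted=False
    )
    trend = np.full(len(y), np.nan)
    trend[obs] = fit_at_obs
    resid = np.full(len(y), np.nan)
    resid[obs] = y[obs] - fit_at_obs
    return DetrendedSeries(
        values=resid,
        fill_mask=miss.copy(),
        trend_fit=trend,
        n_days=series.n_days,
        day_index=series.day_index.copy(),
    )


def amplitude_correct(
    detr: DetrendedSeries, window_days: int = 7, min_range: float = 1e-9
) -> DetrendedSeries:
    """Divide each consecutive block of ``window_days`` by its own range.

    Blocks are aligned to the first day of the series; the final block
    may be shorter.  The range is max - min over non-missing de-trended
    values in the block; blocks with range below ``min_range`` pass
    through unscaled and are flagged invalid.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    n = detr.n_days * 24
    vals = detr.values.copy()
    block_len = window_days * 24
    n_blocks = int(np.ceil(n / block_len))
    valid = np.ones(n_blocks, dtype=bool)
    for b in range(n_blocks):
        sl = slice(b * block_len, min((b + 1) * block_len, n))
        seg = vals[sl]
        obs = ~detr.fill_mask[sl]
        if not obs.any():
            valid[b] = False
            continue
        rng = np.nanmax(seg[obs]) - np.nanmin(seg[obs])
        if rng < min_range:
            valid[b] = False
            continue
        vals[sl] = seg / rng
    return replace(detr, values=vals, block_valid=valid)


def zero_fill(detr: DetrendedSeries) -> DetrendedSeries:
    """Replace missing points by zero, recording them in the fill mask."""
    vals = np.where(detr.fill_mask, 0.0, detr.values)
    return replace(detr, values=vals, filled=True)


def prepare_series(
    series: HourlyIntakeSeries,
    span: float = 0.75,
    window_days: int = 7,
) -> DetrendedSeries:
    """Full stationarising chain: LOESS -> amplitude correction -> zero fill."""
    return zero_fill(amplitude_correct(loess_detrend(series, span=span), window_days))
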