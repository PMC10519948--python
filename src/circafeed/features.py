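"""Diurnal-pattern features extracted from the fitted hurdle model.

Eight features summarise each animal-period: the number of intake peaks,
and the timing, height and width of the highest peak; the lowest intake;
the proportion of intake obtained at night (21:00-05:00); and the lowest
and highest fitted probabilities of eating, which approximate day-to-day
consistency.  All intake quantities are read off the de-trended
prediction (trend spline held at its period mean), in de-trended g/h, so
they are comparable across periods.  The proportion of circadian days
from the wavelet stage joins the table as a ninth column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hurdle_gam import HurdleFit

__all__ = [
    "diurnal_curve",
    "extract_features",
    "features_for_fit",
    "join_circadian",
]

GRID_STEP = 0.1  # hours; sub-6-minute resolution on the diurnal clock
NIGHT_HOURS = (21.0, 5.0)  # intake between 21:00 and 05:00 counts as night


def hour_grid(step: float = GRID_STEP) -> np.ndarray:
    return np.arange(0.0, 24.0, step)


def diurnal_curve(fit: HurdleFit, period_id: int, step: float = GRID_STEP):
    """De-trended predicted-intake and probability curves on a fine grid.

    Returns (grid, f, prob_curve, prob_surface) where ``prob_surface``
    covers the full (day x hour) probability fit of the period.
    """
    grid = hour_grid(step)
    pf = fit.predict_detrended(period_id, grid)
    f = pf["predicted_intake"].to_numpy()
    prob = pf["prob"].to_numpy()
    surface = fit.prob_surface(period_id, grid)
    return grid, f, prob, surface


def _count_peaks_cyclic(f: np.ndarray, prominence_frac: float = 0.05) -> int:
    """Count local maxima of the curve on the circular hour grid.

    With ``prominence_frac > 0``, maxima whose topographic prominence is
    below that fraction of the curve range are ignored — unpenalised
    spline bases introduce small ripples that are not feeding peaks.
    With ``prominence_frac = 0`` every strict increasing-to-decreasing
    sign change of the derivative counts (plateaus count once, via their
    carried sign).
    """
    rng = float(np.max(f) - np.min(f))
    if rng == 0:
        return 0
    if prominence_frac > 0:
        from scipy.signal import find_peaks

        n = len(f)
        ext = np.concatenate([f, f, f])
        peaks, _ = find_peaks(ext, prominence=prominence_frac * rng)
        return int(np.sum((peaks >= n) & (peaks < 2 * n)))
    d = np.diff(np.concatenate([f, f[:1]]))  # cyclic forward differences
    sign = np.sign(d)
    nz = sign != 0
    if not nz.any():
        return 0
    carried = sign.copy()
    last = carried[nz][-1]  # wrap: start from the final non-zero sign
    for i in range(len(carried)):
        if carried[i] == 0:
            carried[i] = last
        else:
            last = carried[i]
    prev = np.roll(carried, 1)
    return int(np.sum((prev > 0) & (carried < 0)))


def extract_features(
    grid: np.ndarray,
    f: np.ndarray,
    prob_curve: np.ndarray,
    prob_surface: np.ndarray | None = None,
    night_mode: str = "trapezoid",
    prominence_frac: float = 0.05,
) -> dict[str, float]:
    """Compute the eight diurnal features from curves on the fine grid.

    Peak width follows the half-hour-flank definition: the mean drop in
    height half an hour before and after the highest peak (larger values
    mean narrower peaks).  Night proportion integrates the curve over
    21:00-05:00 against the full day (``night_mode='binsum'`` switches to
    summing hourly bins).  Probability extremes are taken over the full
    day x hour surface when given, else over the probability curve.
    """
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(prob_curve))):
        raise ValueError("non-finite curve values")
    n = len(grid)
    step = grid[1] - grid[0]
    i_max = int(np.argmax(f))
    half = int(round(0.5 / step))
    width = float(
        ((f[i_max] - f[(i_max - half) % n]) + (f[i_max] - f[(i_max + half) % n])) / 2.0
    )

    if night_mode == "trapezoid":
        closed = np.concatenate([f, f[:1]])
        grid_c = np.concatenate([grid, [24.0]])
        total = np.trapezoid(closed, grid_c)
        # integrate the two night arcs separately (21-24 and 0-5)
        late = grid_c >= NIGHT_HOURS[0]
        early = grid_c <= NIGHT_HOURS[1]
        night = np.trapezoid(closed[late], grid_c[late]) + np.trapezoid(
            closed[early], grid_c[early]
        )
    elif night_mode == "binsum":
        hour_bin = np.floor(grid).astype(int)
        night_sel = (hour_bin >= 21) | (hour_bin <= 4)
        total = float(np.sum(f) * step)
        night = float(np.sum(f[night_sel]) * step)
    else:
        raise ValueError("night_mode must be 'trapezoid' or 'binsum'")

    probs = prob_surface if prob_surface is not None else prob_curve
    return {
        "n_peaks": float(_count_peaks_cyclic(f, prominence_frac)),
        "peak_time_h": float(grid[i_max]),
        "peak_height": float(f[i_max]),
        "peak_width": width,
        "lowest_intake": float(np.min(f)),
        "night_prop": float(night / total) if total > 0 else np.nan,
        "min_prob_eat": float(np.min(probs)),
        "max_prob_eat": float(np.max(probs)),
    }


def features_for_fit(
    fit: HurdleFit, step: float = GRID_STEP, night_mode: str = "trapezoid"
) -> pd.DataFrame:
    """One feature row per retained period of a fitted animal."""
    rows = []
    for p in fit.included_periods:
        grid, f, prob, surface = diurnal_curve(fit, p, step)
        feats = extract_features(grid, f, prob, surface, night_mode=night_mode)
        feats.update({"pig_id": fit.pig_id, "period_id": p})
        rows.append(feats)
    cols = [
        "pig_id", "period_id", "n_peaks", "peak_time_h", "peak_height",
        "peak_width", "lowest_intake", "night_prop", "min_prob_eat", "max_prob_eat",
    ]
    return pd.DataFrame(rows)[cols]


def join_circadian(features: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    """Left-join the per-period proportion of circadian days.

    ``summary`` is the period-grouped rhythm summary (pig_id, group_id,
    proportion_circadian).  Animal-periods absent from the summary, or
    suppressed there for lack of evaluable days, get NaN and drop out of
    downstream correlations.
    """
    s = summary.rename(columns={"group_id": "period_id"})[
        ["pig_id", "period_id", "proportion_circadian"]
    ].rename(columns={"proportion_circadian": "prop_circadian_days"})
    return features.merge(s, on=["pig_id", "period_id"], how="left")
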