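"""Central time-series container: per-animal hourly feed intake.

The whole pipeline revolves around one object per animal: a day x 24 matrix
of hourly feed intake in grams with an explicit missingness mask.  Hour bin
``h`` covers the half-open interval ``[h, h+1)`` hours post-midnight; day
boundaries fall at 00:00.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["HourlyIntakeSeries", "series_to_frame", "frame_to_series"]


@dataclass
class HourlyIntakeSeries:
    """Hourly feed intake of one animal over the study window.

    Parameters
    ----------
    pig_id, pen_id
        Animal and pen identifiers.
    values
        ``(n_days, 24)`` array of intake in grams.  Entries under the
        missing mask are not interpreted (conventionally NaN).
    missing_mask
        ``(n_days, 24)`` boolean array; True marks hours with no valid
        recording (removed days, feeder malfunction).
    day_index
        Day numbers since arrival at the farm, length ``n_days``.
    truth
        Optional ground-truth payload attached by the simulator
        (generating profile and parameters); None for real data.
    """

    pig_id: str
    pen_id: str
    values: np.ndarray
    missing_mask: np.ndarray
    day_index: np.ndarray
    truth: dict[str, Any] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.day_index = np.asarray(self.day_index, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != 24:
            raise ValueError("values must have shape (n_days, 24)")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if len(self.day_index) != self.values.shape[0]:
            raise ValueError("day_index length must equal n_days")
        obs = ~self.missing_mask
        if np.any(self.values[obs] < 0):
            raise ValueError("observed intake values must be non-negative")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "HourlyIntakeSeries":
        return HourlyIntakeSeries(
            pig_id=self.pig_id,
            pen_id=self.pen_id,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            day_index=self.day_index.copy(),
            truth=self.truth,
        )

    def flat_values(self) -> np.ndarray:
        """Row-major flattening (day-major, hour-minor), length n_days*24."""
        return self.values.reshape(-1)

    def flat_missing(self) -> np.ndarray:
        return self.missing_mask.reshape(-1)

    def total_intake(self) -> float:
        """Sum of intake over non-missing hours, in grams."""
        return float(np.nansum(np.where(self.missing_mask, 0.0, self.values)))


def series_to_frame(series_list: list[HourlyIntakeSeries]) -> pd.DataFrame:
    """Tidy representation: one row per (pig, day, hour)."""
    frames = []
    for s in series_list:
        n = s.n_days
        frames.append(
            pd.DataFrame(
                {
                    "pig_id": s.pig_id,
                    "pen_id": s.pen_id,
                    "day": np.repeat(s.day_index, 24),
                    "hour": np.tile(np.arange(24), n),
                    "intake_g": s.flat_values(),
                    "missing": s.flat_missing(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_series(df: pd.DataFrame) -> list[HourlyIntakeSeries]:
    """Inverse of :func:`series_to_frame`."""
    out = []
    for (pig, pen), g in df.groupby(["pig_id", "pen_id"], sort=True):
        days = np.sort(g["day"].unique())
        day_pos = {d: i for i, d in enumerate(days)}
        vals = np.full((len(days), 24), np.nan)
        miss = np.ones((len(days), 24), dtype=bool)
        rows = [day_pos[d] for d in g["day"].to_numpy()]
        cols = g["hour"].to_numpy()
        vals[rows, cols] = g["intake_g"].to_numpy()
        miss[rows, cols] = g["missing"].to_numpy(dtype=bool)
        vals[miss] = np.nan
        out.append(
            HourlyIntakeSeries(
                pig_id=str(pig), pen_id=str(pen),
                values=vals, missing_mask=miss, day_index=days,
            )
        )
    return out
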