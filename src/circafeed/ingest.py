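"""Visit cleaning, welfare-day filters and hourly aggregation.

Electronic feeding stations occasionally log impossible visits (negative
intakes from load-cell drift, implausible feeding rates, stuck-open
records).  This module removes them with a parameterised rule set, drops
whole pig-days that were dominated by bad records, masks days around
welfare events, and aggregates the surviving visits into each animal's
hourly intake matrix.  Intake is held in grams throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import HourlyIntakeSeries

__all__ = [
    "CleaningRules",
    "CleaningReport",
    "WelfareEvents",
    "parse_visits",
    "clean_visits",
    "filter_pig_days",
    "aggregate_hourly",
]

RULE_NAMES = ("neg_intake", "rate_max", "duration", "overlap", "bad_day")


@dataclass(frozen=True)
class CleaningRules:
    """Thresholds for the visit-cleaning rules (all configurable).

    tol : grams; intakes below ``-tol`` are removed and a zero-duration
        visit may carry at most ``tol`` grams.
    rate_max : g/min; visits implying a faster feeding rate are removed.
    dur_max : seconds; visits longer than this are removed.
    day_frac_max : if more than this fraction of a pig-day's visits were
        removed by the per-visit rules, the whole pig-day is dropped to
        avoid biased hourly sums.
    """

    tol: float = 0.0
    rate_max: float = 150.0
    dur_max: float = 3600.0
    day_frac_max: float = 0.25
    enable_neg_intake: bool = True
    enable_rate_max: bool = True
    enable_duration: bool = True
    enable_overlap: bool = True
    enable_bad_day: bool = True


@dataclass
class CleaningReport:
    n_visits_in: int = 0
    n_removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_pig_days_removed: int = 0
    n_quarantined: int = 0
    fraction_intake_removed: float = 0.0
    removed_pig_days: set = field(default_factory=set)

    @property
    def n_visits_removed(self) -> int:
        return sum(self.n_removed_by_rule.values())


@dataclass
class WelfareEvents:
    """Day-level welfare information used to mask non-basal feeding days.

    disease_days maps pig_id -> day numbers with a high disease score;
    first_obs_day is the first day of health observations (cohort level);
    slaughter_day is the day the first batch left for slaughter.
    """

    disease_days: dict[str, list[int]] = field(default_factory=dict)
    first_obs_day: int | None = None
    slaughter_day: int | None = None
    disease_window: int = 3

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "WelfareEvents":
        """Build from a tidy table (pig_id, event_type, day).

        Recognised event types: ``disease`` (per pig), ``first_obs`` and
        ``slaughter`` (pig_id ignored).
        """
        ev = cls(**kwargs)
        for _, row in df.iterrows():
            kind = str(row["event_type"])
            day = int(row["day"])
            if kind == "disease":
                ev.disease_days.setdefault(str(row["pig_id"]), []).append(day)
            elif kind == "first_obs":
                ev.first_obs_day = day
            elif kind == "slaughter":
                ev.slaughter_day = day
            else:
                raise ValueError(f"unknown event_type {kind!r}")
        return ev


def parse_visits(path_or_df) -> tuple[pd.DataFrame, int]:
    """Read a visit CSV, quarantining unparseable rows.

    Returns (clean frame, number of quarantined rows).  Expected columns:
    pig_id, pen_id, entry_ts, exit_ts, intake_g.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    required = ["pig_id", "pen_id", "entry_ts", "exit_ts", "intake_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"visit table lacks columns {missing}")
    entry = pd.to_datetime(df["entry_ts"], errors="coerce")
    exit_ = pd.to_datetime(df["exit_ts"], errors="coerce")
    intake = pd.to_numeric(df["intake_g"], errors="coerce")
    bad = entry.isna() | exit_.isna() | intake.isna() | (exit_ < entry)
    out = df.loc[~bad].copy()
    out["entry_ts"] = entry[~bad]
    out["exit_ts"] = exit_[~bad]
    out["intake_g"] = intake[~bad]
    out["duration_s"] = (out["exit_ts"] - out["entry_ts"]).dt.total_seconds()
    return out.reset_index(drop=True), int(bad.sum())


def clean_visits(
    visits: pd.DataFrame, rules: CleaningRules = CleaningRules()
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the per-visit rules, then drop pig-days dominated by removals.

    Each removed visit is attributed to the first rule that caught it, so
    the per-rule tallies partition the removals.  Rule order: negative
    intake, feeding rate, duration, same-pig overlap, then the whole-day
    sweep.
    """
    df, n_quar = parse_visits(visits)
    report = CleaningReport(n_visits_in=len(df), n_quarantined=n_quar)
    report.n_removed_by_rule = {r: 0 for r in RULE_NAMES}
    total_intake = float(df.loc[df["intake_g"] > 0, "intake_g"].sum())

    reason = pd.Series("", index=df.index, dtype=object)

    if rules.enable_neg_intake:
        hit = (df["intake_g"] < -rules.tol) & (reason == "")
        reason[hit] = "neg_intake"
    if rules.enable_rate_max:
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(
                df["duration_s"] > 0, df["intake_g"] / (df["duration_s"] / 60.0), np.inf
            )
        hit = (df["intake_g"] > rules.tol) & (rate > rules.rate_max) & (reason == "")
        reason[hit] = "rate_max"
    if rules.enable_duration:
        hit = (
            (df["duration_s"] > rules.dur_max)
            | ((df["duration_s"] == 0) & (df["intake_g"] > rules.tol))
        ) & (reason == "")
        reason[hit] = "duration"
    if rules.enable_overlap:
        order = df.sort_values(["pig_id", "entry_ts"]).index
        last_exit: dict[str, pd.Timestamp] = {}
        for idx in order:
            pig = df.at[idx, "pig_id"]
            if reason[idx] != "":
                continue
            prev = last_exit.get(pig)
            if prev is not None and df.at[idx, "entry_ts"] < prev:
                reason[idx] = "overlap"
                continue
            last_exit[pig] = df.at[idx, "exit_ts"]

    if rules.enable_bad_day:
        day = df["entry_ts"].dt.normalize()
        key = list(zip(df["pig_id"], day))
        removed = reason != ""
        frame = pd.DataFrame({"key": key, "removed": removed})
        frac = frame.groupby("key")["removed"].mean()
        bad_days = set(frac.index[frac > rules.day_frac_max])
        hit = pd.Series([k in bad_days for k in key], index=df.index) & (reason == "")
        reason[hit] = "bad_day"
        report.n_pig_days_removed = len(bad_days)
        report.removed_pig_days = bad_days

    for r in RULE_NAMES:
        report.n_removed_by_rule[r] = int((reason == r).sum())
    kept = df.loc[reason == ""].copy()
    removed_intake = float(
        df.loc[(reason != "") & (df["intake_g"] > 0), "intake_g"].sum()
    )
    report.fraction_intake_removed = (
        removed_intake / total_intake if total_intake > 0 else 0.0
    )
    return kept.reset_index(drop=True), report


def filter_pig_days(
    hourly: HourlyIntakeSeries, events: WelfareEvents
) -> tuple[HourlyIntakeSeries, int]:
    """Mask non-basal days: around disease, before first health
    observation, after first slaughter departure.

    Disease days are masked together with the ``disease_window`` days on
    either side (inclusive).  Days strictly before ``first_obs_day`` and
    strictly after ``slaughter_day`` are masked.  Idempotent.  Returns
    the filtered copy and the number of newly masked days.
    """
    out = hourly.copy()
    days = out.day_index
    mask_day = np.zeros(out.n_days, dtype=bool)
    w = events.disease_window
    for d in events.disease_days.get(hourly.pig_id, []):
        mask_day |= (days >= d - w) & (days <= d + w)
    if events.first_obs_day is not None:
        mask_day |= days < events.first_obs_day
    if events.slaughter_day is not None:
        mask_day |= days > events.slaughter_day
    newly = int(np.sum(mask_day & ~out.missing_mask.all(axis=1)))
    out.missing_mask[mask_day, :] = True
    out.values[mask_day, :] = np.nan
    return out, newly


def aggregate_hourly(
    visits: pd.DataFrame,
    start_date: str | pd.Timestamp,
    n_days: int,
    first_day: int = 1,
    removed_pig_days: set | None = None,
) -> list[HourlyIntakeSeries]:
    """Sum visit intakes into per-animal (day x 24) matrices.

    A visit spanning an hour boundary contributes to each hour bin in
    proportion to the time it spent there.  Hours on pig-days removed by
    the cleaning sweep are marked missing; hours without visits on
    retained days are zero.  ``first_day`` is the day number assigned to
    ``start_date``.
    """
    start = pd.Timestamp(start_date)
    removed_pig_days = removed_pig_days or set()
    out = []
    for (pig, pen), g in visits.groupby(["pig_id", "pen_id"], sort=True):
        vals = np.zeros((n_days, 24))
        miss = np.zeros((n_days, 24), dtype=bool)
        entry = g["entry_ts"]
        exit_ = g["exit_ts"]
        hour_end = entry.dt.floor("h") + pd.Timedelta(hours=1)
        spans = (exit_ > hour_end).to_numpy()

        # fast path: visit fully inside one hour bin
        simple = g.loc[~spans]
        if len(simple):
            d = ((simple["entry_ts"].dt.normalize() - start).dt.days).to_numpy()
            h = simple["entry_ts"].dt.hour.to_numpy()
            ok = (d >= 0) & (d < n_days)
            np.add.at(vals, (d[ok], h[ok]), simple["intake_g"].to_numpy()[ok])

        # slow path: split across hour bins proportionally to time spent
        for _, row in g.loc[spans].iterrows():
            e0, e1 = row["entry_ts"], row["exit_ts"]
            intake = float(row["intake_g"])
            total_s = max((e1 - e0).total_seconds(), 0.0)
            t = e0
            while True:
                next_edge = t.floor("h") + pd.Timedelta(hours=1)
                seg_end = min(next_edge, e1)
                seg_s = (seg_end - t).total_seconds()
                w = seg_s / total_s if total_s > 0 else 1.0
                d = (t.normalize() - start).days
                h = t.hour
                if 0 <= d < n_days:
                    vals[d, h] += intake * w
                if seg_end >= e1:
                    break
                t = seg_end
        for pig_day in removed_pig_days:
            p, day_ts = pig_day
            if p != pig:
                continue
            d = (pd.Timestamp(day_ts) - start).days
            if 0 <= d < n_days:
                miss[d, :] = True
                vals[d, :] = np.nan
        out.append(
            HourlyIntakeSeries(
                pig_id=str(pig),
                pen_id=str(pen),
                values=vals,
                missing_mask=miss,
                day_index=np.arange(first_day, first_day + n_days),
            )
        )
    return out
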