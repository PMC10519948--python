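"""Synthetic electronic-feeding-station cohorts with known ground truth.

Emulates the study design this pipeline targets: pens of growing-finishing
pigs on single-space electronic feeders, recorded over one fattening phase
(default 10 pens x 11 pigs x 83 days).  Each animal carries a diurnal
profile — hourly probabilities of eating and conditional mean intakes —
from which hourly intake is drawn with a hurdle (Bernoulli x gamma)
mechanism, a multiplicative growth trend, day-to-day jitter controlled by a
consistency parameter, and whole missing days.  Hourly values can be
exploded into realistic visit records and corrupted with injectable
recording errors, so that every cleaning and modelling stage downstream is
testable against programmed truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .series import HourlyIntakeSeries

__all__ = [
    "DiurnalProfile",
    "CohortSpec",
    "ErrorInjectionSpec",
    "alternans_profile",
    "cosine_profile",
    "single_peak_profile",
    "night_feeder_profile",
    "flat_profile",
    "make_profile",
    "generate_hourly",
    "generate_visits",
    "inject_errors",
    "simulate_cohort",
    "cohort_visits",
    "write_cohort",
]

PATTERN_KINDS = ("alternans", "single_peak", "night_feeder", "flat")


@dataclass(frozen=True)
class DiurnalProfile:
    """Ground-truth within-day feeding structure of one animal.

    ``p_eat[h]`` is the probability the animal eats during hour bin ``h``;
    ``mu_intake[h]`` the mean positive intake (g) conditional on eating.
    ``consistency`` in [0, 1] scales down the day-to-day jitter of the
    profile: 1 means the same profile is replayed every day, 0 means
    heavily perturbed timing and propensity from day to day.
    """

    pattern_kind: str
    p_eat: np.ndarray
    mu_intake: np.ndarray
    consistency: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_eat", np.asarray(self.p_eat, dtype=float))
        object.__setattr__(self, "mu_intake", np.asarray(self.mu_intake, dtype=float))
        if self.pattern_kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")
        if self.p_eat.shape != (24,) or self.mu_intake.shape != (24,):
            raise ValueError("p_eat and mu_intake must be vectors of length 24")
        if np.any((self.p_eat < 0) | (self.p_eat > 1)):
            raise ValueError("p_eat entries must lie in [0, 1]")
        if np.any(self.mu_intake < 0):
            raise ValueError("mu_intake entries must be non-negative")
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must lie in [0, 1]")

    def expected_hourly(self) -> np.ndarray:
        """Marginal expected intake per hour at trend 1 (g)."""
        return self.p_eat * self.mu_intake


def _bump(hours: np.ndarray, centre: float, width: float) -> np.ndarray:
    """Circular Gaussian bump on the 24 h clock."""
    d = np.minimum(np.abs(hours - centre), 24.0 - np.abs(hours - centre))
    return np.exp(-0.5 * (d / width) ** 2)


def alternans_profile(consistency: float = 0.8) -> DiurnalProfile:
    """Small morning peak (~09:00) plus larger afternoon peak (~16:30)."""
    h = np.arange(24) + 0.5
    shape = 0.55 * _bump(h, 9.0, 1.4) + 1.0 * _bump(h, 16.5, 1.8)
    p = np.clip(0.08 + 0.82 * shape / shape.max(), 0, 1)
    mu = 40.0 + 180.0 * shape / shape.max()
    return DiurnalProfile("alternans", p, mu, consistency)


def single_peak_profile(consistency: float = 0.8, peak_hour: float = 16.0) -> DiurnalProfile:
    """One afternoon feeding peak, little activity otherwise."""
    h = np.arange(24) + 0.5
    shape = _bump(h, peak_hour, 2.5)
    p = np.clip(0.05 + 0.85 * shape, 0, 1)
    mu = 35.0 + 220.0 * shape
    return DiurnalProfile("single_peak", p, mu, consistency)


def cosine_profile(
    consistency: float = 1.0, peak_hour: float = 16.0
) -> DiurnalProfile:
    """Smooth single-peak profile with moderate eating probabilities.

    p_eat stays within [0.3, 0.75], so every hour-by-period cell sees
    several eating events in a 14-day period — the regime in which
    chi-square reference distributions for model comparisons are
    accurate.  The canonical null profile for calibration studies.
    """
    h = np.arange(24) + 0.5
    c = 0.5 + 0.5 * np.cos(2 * np.pi * (h - peak_hour) / 24.0)
    return DiurnalProfile("single_peak", 0.3 + 0.45 * c, 80.0 + 120.0 * c, consistency)


def night_feeder_profile(consistency: float = 0.5) -> DiurnalProfile:
    """Feeding concentrated between ~22:00 and ~04:00."""
    h = np.arange(24) + 0.5
    shape = _bump(h, 1.0, 3.0)
    p = np.clip(0.10 + 0.65 * shape, 0, 1)
    mu = 45.0 + 140.0 * shape
    return DiurnalProfile("night_feeder", p, mu, consistency)


def flat_profile(consistency: float = 0.3, p: float = 0.45, mu: float = 90.0) -> DiurnalProfile:
    """Irregular eater: uniform probability and intake across the day."""
    return DiurnalProfile("flat", np.full(24, p), np.full(24, mu), consistency)


_FACTORIES: dict[str, Callable[..., DiurnalProfile]] = {
    "alternans": alternans_profile,
    "single_peak": single_peak_profile,
    "night_feeder": night_feeder_profile,
    "flat": flat_profile,
}


def make_profile(kind: str, **kwargs) -> DiurnalProfile:
    return _FACTORIES[kind](**kwargs)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort.

    Defaults mirror a single fattening round: 10 pens of 11 pigs monitored
    for 83 days, daily intake ramping up 2.5-fold with growth.  ``trend``
    maps day number to a multiplicative intake factor; the default is a
    linear ramp from ``trend_range[0]`` to ``trend_range[1]`` across the
    phase.  ``sigma_pig`` / ``sigma_pen`` are log-scale standard deviations
    of animal- and pen-level multiplicative offsets on mean intake.
    ``ar1_rho`` is the programmed period-to-period residual correlation
    used when simulating feature panels for the variance-component stage.
    """

    n_pens: int = 10
    pigs_per_pen: int = 11
    n_days: int = 83
    trend_range: tuple[float, float] = (1.0, 2.5)
    trend: Callable[[np.ndarray], np.ndarray] | None = None
    sigma_pig: float = 0.10
    sigma_pen: float = 0.05
    ar1_rho: float = 0.3
    missing_day_prob: float = 0.05
    gamma_shape: float = 4.0
    jitter_logit_sd: float = 1.2
    jitter_log_sd: float = 0.35
    phase_jitter_sd_h: float = 5.0
    first_day: int = 1
    start_date: str = "2020-12-15"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pens, self.pigs_per_pen, self.n_days) < 1:
            raise ValueError("n_pens, pigs_per_pen and n_days must be >= 1")
        if not 0.0 <= self.missing_day_prob <= 1.0:
            raise ValueError("missing_day_prob must lie in [0, 1]")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def trend_factor(self, day: np.ndarray) -> np.ndarray:
        """Multiplicative daily-intake factor for day numbers ``day``."""
        day = np.asarray(day, dtype=float)
        if self.trend is not None:
            return np.asarray(self.trend(day), dtype=float)
        lo, hi = self.trend_range
        span = max(self.n_days - 1, 1)
        frac = (day - self.first_day) / span
        return lo + (hi - lo) * np.clip(frac, 0.0, 1.0)


@dataclass(frozen=True)
class ErrorInjectionSpec:
    """Per-visit probabilities of injecting each class of recording error.

    The three classes are mutually exclusive per visit: a negative-intake
    registration, an implausibly fast feeding rate, and an implausibly
    long visit.  Rates must sum to at most 1.
    """

    neg_intake_rate: float = 0.0
    rate_spike_rate: float = 0.0
    long_visit_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.neg_intake_rate, self.rate_spike_rate, self.long_visit_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("error rates must lie in [0, 1]")
        if sum(rates) > 1.0 + 1e-12:
            raise ValueError("error rates must sum to at most 1")


def _pig_rng(spec: CohortSpec, pen_index: int, pig_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1 + pen_index, 1 + pig_index])


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def generate_hourly(
    profile: DiurnalProfile,
    spec: CohortSpec,
    pig_index: int = 0,
    pen_index: int = 0,
) -> HourlyIntakeSeries:
    """Draw one animal's hourly intake matrix from its diurnal profile.

    For each hour of each day the animal eats with (jittered) probability
    ``p_eat[h]``; conditional on eating, intake is gamma with mean
    ``trend(day) * mu_intake[h]`` (times pen/pig offsets and day jitter)
    and shape ``spec.gamma_shape``.  Day-to-day jitter consists of a
    day-level propensity shift on the logit scale, a day-level intake
    shift on the log scale, and a circular phase shift of the whole
    profile in whole hours — all scaled by ``1 - consistency``.  Whole
    days go missing with probability ``missing_day_prob``.
    """
    rng = _pig_rng(spec, pen_index, pig_index)
    jit = 1.0 - profile.consistency
    sd_logit = spec.jitter_logit_sd * jit
    sd_log = spec.jitter_log_sd * jit
    sd_phase = spec.phase_jitter_sd_h * jit

    pen_rng = np.random.default_rng([spec.seed, 1 + pen_index])
    pen_f = float(np.exp(pen_rng.normal(0.0, spec.sigma_pen))) if spec.sigma_pen > 0 else 1.0
    pig_f = float(np.exp(rng.normal(0.0, spec.sigma_pig))) if spec.sigma_pig > 0 else 1.0

    days = np.arange(spec.first_day, spec.first_day + spec.n_days)
    trend = spec.trend_factor(days)
    values = np.zeros((spec.n_days, 24))
    missing = np.zeros((spec.n_days, 24), dtype=bool)

    for d in range(spec.n_days):
        if spec.missing_day_prob > 0 and rng.random() < spec.missing_day_prob:
            missing[d, :] = True
            values[d, :] = np.nan
            continue
        shift = int(np.round(rng.normal(0.0, sd_phase))) % 24 if sd_phase > 0 else 0
        p_day = np.roll(profile.p_eat, shift)
        mu_day = np.roll(profile.mu_intake, shift)
        if sd_logit > 0:
            p_day = 1.0 / (1.0 + np.exp(-(_logit(p_day) + rng.normal(0.0, sd_logit))))
        if sd_log > 0:
            # mean-preserving lognormal day factor
            mu_day = mu_day * np.exp(rng.normal(0.0, sd_log) - 0.5 * sd_log**2)
        eats = rng.random(24) < p_day
        mean = trend[d] * pen_f * pig_f * mu_day
        k = spec.gamma_shape
        amounts = np.where(mean > 0, rng.gamma(k, np.maximum(mean, 1e-12) / k), 0.0)
        values[d, :] = np.where(eats, amounts, 0.0)

    return HourlyIntakeSeries(
        pig_id=f"pig{pen_index:02d}{pig_index:02d}",
        pen_id=f"pen{pen_index:02d}",
        values=values,
        missing_mask=missing,
        day_index=days,
        truth={
            "profile": profile,
            "trend": trend,
            "pen_factor": pen_f,
            "pig_factor": pig_f,
            "pen_index": pen_index,
            "pig_index": pig_index,
        },
    )


# dyadic split weights keep visit intakes exactly summable in binary float
_SPLIT_WEIGHTS = {1: (1.0,), 2: (0.5, 0.5), 3: (0.25, 0.25, 0.5)}


def generate_visits(hourly: HourlyIntakeSeries, spec: CohortSpec) -> pd.DataFrame:
    """Explode an hourly matrix into feeder-visit records.

    Each non-zero hour becomes 1-3 visits whose intakes sum exactly to the
    hourly value (dyadic split weights make the float sum exact, so the
    visit -> hourly round trip is bit-faithful).  Timestamps are placed in
    disjoint slots inside the hour.  Missing hours emit no visits.
    """
    if hourly.truth is not None:
        ident = [1 + int(hourly.truth["pen_index"]), 1 + int(hourly.truth["pig_index"])]
    else:
        import zlib

        ident = [zlib.crc32(hourly.pig_id.encode())]
    rng = np.random.default_rng([spec.seed, 7, *ident])
    start = pd.Timestamp(spec.start_date)
    rows: list[tuple] = []
    for d in range(hourly.n_days):
        day_no = int(hourly.day_index[d])
        for h in range(24):
            if hourly.missing_mask[d, h]:
                continue
            total = hourly.values[d, h]
            if total <= 0:
                continue
            k = int(rng.integers(1, 4))
            weights = _SPLIT_WEIGHTS[k]
            slot = 3600.0 / k
            base = start + pd.Timedelta(days=day_no - spec.first_day, hours=h)
            for i, w in enumerate(weights):
                intake = total * w
                rate = rng.uniform(25.0, 40.0)  # g/min
                entry_off = slot * i + rng.uniform(0.0, 0.15 * slot)
                dur = min(intake / rate * 60.0, 0.8 * slot)
                dur = max(dur, 5.0)
                rows.append(
                    (
                        hourly.pig_id,
                        hourly.pen_id,
                        base + pd.Timedelta(seconds=entry_off),
                        base + pd.Timedelta(seconds=entry_off + dur),
                        intake,
                    )
                )
    return pd.DataFrame(rows, columns=["pig_id", "pen_id", "entry_ts", "exit_ts", "intake_g"])


def inject_errors(
    visits: pd.DataFrame, err: ErrorInjectionSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Corrupt a visit table with seeded recording errors.

    Returns the corrupted table and a per-record label series taking
    values ``clean``, ``neg_intake``, ``rate_spike`` or ``long_visit``.
    Error classes are mutually exclusive per visit, drawn from one
    uniform variate against the cumulative rates.
    """
    rng = np.random.default_rng(err.seed)
    out = visits.copy().reset_index(drop=True)
    n = len(out)
    u = rng.random(n)
    r1, r2, r3 = err.neg_intake_rate, err.rate_spike_rate, err.long_visit_rate
    labels = np.full(n, "clean", dtype=object)
    labels[u < r1] = "neg_intake"
    labels[(u >= r1) & (u < r1 + r2)] = "rate_spike"
    labels[(u >= r1 + r2) & (u < r1 + r2 + r3)] = "long_visit"

    neg = labels == "neg_intake"
    out.loc[neg, "intake_g"] = -(np.abs(out.loc[neg, "intake_g"]) + 10.0)

    spike = labels == "rate_spike"
    if spike.any():
        # shrink duration so the implied rate lands near 400 g/min
        dur = out.loc[spike, "intake_g"].to_numpy() / 400.0 * 60.0
        out.loc[spike, "exit_ts"] = out.loc[spike, "entry_ts"] + pd.to_timedelta(
            np.maximum(dur, 1.0), unit="s"
        )

    long_v = labels == "long_visit"
    if long_v.any():
        out.loc[long_v, "exit_ts"] = out.loc[long_v, "entry_ts"] + pd.Timedelta(hours=2)

    return out, pd.Series(labels, name="truth_label")


def simulate_cohort(
    spec: CohortSpec,
    profile_for: Callable[[int, int], DiurnalProfile] | Sequence[DiurnalProfile] | None = None,
) -> list[HourlyIntakeSeries]:
    """Generate every animal of a cohort.

    ``profile_for`` maps (pen_index, pig_index) to a profile, or is a flat
    sequence cycled over animals; by default the four canonical pattern
    kinds are cycled so the cohort mixes alternans, single-peak,
    night-feeding and flat/irregular animals.
    """
    if profile_for is None:
        kinds = [make_profile(k) for k in PATTERN_KINDS]

        def profile_for_fn(pen: int, pig: int) -> DiurnalProfile:
            return kinds[(pen * spec.pigs_per_pen + pig) % len(kinds)]

    elif callable(profile_for):
        profile_for_fn = profile_for
    else:
        seq = list(profile_for)

        def profile_for_fn(pen: int, pig: int) -> DiurnalProfile:
            return seq[(pen * spec.pigs_per_pen + pig) % len(seq)]

    cohort = []
    for pen in range(spec.n_pens):
        for pig in range(spec.pigs_per_pen):
            prof = profile_for_fn(pen, pig)
            cohort.append(generate_hourly(prof, spec, pig_index=pig, pen_index=pen))
    return cohort


def simulate_feature_panel(
    n_pens: int = 10,
    pigs_per_pen: int = 11,
    n_periods: int = 5,
    period_means: Sequence[float] | None = None,
    var_pen: float = 0.25,
    var_pig: float = 1.0,
    var_resid: float = 0.75,
    rho: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a feature panel with known variance components.

    y = period mean + pen intercept + pig intercept + AR(1) residual
    across periods within pig.  Used to validate the variance-component
    and ICC machinery against programmed truth.  Returns columns pen,
    pig, period, value.
    """
    rng = np.random.default_rng(seed)
    means = np.zeros(n_periods) if period_means is None else np.asarray(period_means, float)
    rows = []
    for pen in range(n_pens):
        b_pen = rng.normal(0.0, np.sqrt(var_pen))
        for pig in range(pigs_per_pen):
            b_pig = rng.normal(0.0, np.sqrt(var_pig))
            e = np.empty(n_periods)
            e[0] = rng.normal(0.0, np.sqrt(var_resid))
            for t in range(1, n_periods):
                e[t] = rho * e[t - 1] + rng.normal(
                    0.0, np.sqrt(var_resid * (1.0 - rho**2))
                )
            for t in range(n_periods):
                rows.append(
                    {
                        "pen": f"pen{pen:02d}",
                        "pig": f"pig{pen:02d}{pig:02d}",
                        "period": t + 1,
                        "value": means[t] + b_pen + b_pig + e[t],
                    }
                )
    return pd.DataFrame(rows)


def cohort_visits(cohort: list[HourlyIntakeSeries], spec: CohortSpec) -> pd.DataFrame:
    frames = [generate_visits(s, spec) for s in cohort]
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: list[HourlyIntakeSeries], spec: CohortSpec, outdir) -> None:
    """Write visit CSV plus a ground-truth JSON sidecar."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    visits = cohort_visits(cohort, spec)
    visits.to_csv(outdir / "visits.csv", index=False)
    truth = {}
    for s in cohort:
        t = s.truth or {}
        prof = t.get("profile")
        truth[s.pig_id] = {
            "pen_id": s.pen_id,
            "pattern_kind": prof.pattern_kind if prof else None,
            "consistency": prof.consistency if prof else None,
            "p_eat": prof.p_eat.tolist() if prof else None,
            "mu_intake": prof.mu_intake.tolist() if prof else None,
            "missing_days": s.day_index[s.missing_mask.all(axis=1)].tolist(),
        }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
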