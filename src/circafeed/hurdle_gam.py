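"""Two-part (hurdle) diurnal model of hourly feed intake, fitted per animal.

Hourly intake mixes a point mass at zero (hours without feeding) with a
positive continuous amount, so the model factorises into a binary part —
probability of eating in an hour, logistic GAM — and a positive part —
mean intake given eating, gamma GAM with log link.  Both parts share one
structure: a spline trend across days plus a cyclic diurnal spline in
hour, the latter fitted separately for each 14-day period so the
within-day shape may change with age.  Expected intake is the product of
the two fitted surfaces.  Because the two likelihood factors share no
parameters they are fitted independently; the total log-likelihood is
their sum, which is exactly the zero-adjusted gamma likelihood.

Splines are unpenalised regression splines of fixed dimension (cyclic
diurnal basis from 8 knots on the 24 h circle, trend basis from 4 knots
across days), which keeps likelihood-ratio comparisons between nested
model variants standard chi-square tests with integer degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy.optimize import brentq
from scipy.special import digamma, gammaln
import statsmodels.api as sm

from .series import HourlyIntakeSeries

__all__ = [
    "assign_periods",
    "period_availability",
    "series_to_model_frame",
    "HurdleFit",
    "fit_hurdle",
    "LRResult",
    "lr_compare",
]

MIN_DAYS_PER_PERIOD = 7


def assign_periods(
    first_day: int, last_day: int, period_len: int = 14
) -> pd.DataFrame:
    """Consecutive ``period_len``-day blocks across the cohort window.

    The final partial block is kept as its own (shorter) period.
    Returns columns period_id, day_start, day_end, n_days.
    """
    rows = []
    pid = 1
    d = first_day
    while d <= last_day:
        end = min(d + period_len - 1, last_day)
        rows.append({"period_id": pid, "day_start": d, "day_end": end, "n_days": end - d + 1})
        pid += 1
        d = end + 1
    return pd.DataFrame(rows)


def period_availability(
    series: HourlyIntakeSeries, periods: pd.DataFrame, min_days: int = MIN_DAYS_PER_PERIOD
) -> pd.DataFrame:
    """Count non-missing days per period and flag inclusion (>= min_days)."""
    day_ok = ~series.missing_mask.all(axis=1)
    rows = []
    for _, p in periods.iterrows():
        sel = (series.day_index >= p["day_start"]) & (series.day_index <= p["day_end"])
        n = int(np.sum(day_ok & sel))
        rows.append(
            {
                "pig_id": series.pig_id,
                "period_id": int(p["period_id"]),
                "n_available_days": n,
                "included": n >= min_days,
            }
        )
    return pd.DataFrame(rows)


def series_to_model_frame(
    series: HourlyIntakeSeries, periods: pd.DataFrame
) -> pd.DataFrame:
    """Long frame of observed hours: day, hour midpoint, period, intake."""
    n = series.n_days
    day = np.repeat(series.day_index, 24)
    hour = np.tile(np.arange(24) + 0.5, n)  # bin midpoint as covariate
    intake = series.flat_values()
    obs = ~series.flat_missing()
    df = pd.DataFrame(
        {"day": day[obs], "hour": hour[obs], "intake_g": intake[obs]}
    )
    df["eat"] = (df["intake_g"] > 0).astype(float)
    df["period_id"] = 0
    for _, p in periods.iterrows():
        sel = (df["day"] >= p["day_start"]) & (df["day"] <= p["day_end"])
        df.loc[sel, "period_id"] = int(p["period_id"])
    return df[df["period_id"] > 0].reset_index(drop=True)


_CC_FORMULA = "cc(hour, df=6, constraints='center', lower_bound=0, upper_bound=24) - 1"
_BS_FORMULA = "bs(day, df=3, degree=3) - 1"


class _DesignBuilder:
    """Assemble hurdle design matrices and rebuild them for prediction.

    Columns: intercept | day trend basis | diurnal block(s).  The full
    model gets one centred cyclic block per included period; the
    single-diurnal variant one shared block; the trend-only variant none.
    """

    def __init__(self, frame: pd.DataFrame, kind: str, included: Sequence[int]):
        if kind not in ("full", "single_diurnal", "trend_only"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.included = list(included)
        cc = patsy.dmatrix(_CC_FORMULA, frame)
        bs = patsy.dmatrix(_BS_FORMULA, frame)
        self._cc_info = cc.design_info
        self._bs_info = bs.design_info
        self.n_cc = cc.shape[1]
        self.n_bs = bs.shape[1]

    def matrix(self, frame: pd.DataFrame) -> np.ndarray:
        cc = np.asarray(
            patsy.build_design_matrices([self._cc_info], frame)[0]
        )
        bs = np.asarray(
            patsy.build_design_matrices([self._bs_info], frame)[0]
        )
        cols = [np.ones((len(frame), 1)), bs]
        if self.kind == "single_diurnal":
            cols.append(cc)
        elif self.kind == "full":
            pid = frame["period_id"].to_numpy()
            for p in self.included:
                cols.append(cc * (pid == p)[:, None])
        return np.hstack(cols)

    def matrix_mean_trend(self, frame: pd.DataFrame, trend_row: np.ndarray) -> np.ndarray:
        """Like :meth:`matrix` but with the day-trend basis replaced by a
        fixed row (e.g. the period mean), removing the trend contribution
        variation."""
        X = self.matrix(frame)
        X[:, 1 : 1 + self.n_bs] = trend_row[None, :]
        return X

    @property
    def n_params(self) -> int:
        n = 1 + self.n_bs
        if self.kind == "single_diurnal":
            n += self.n_cc
        elif self.kind == "full":
            n += self.n_cc * len(self.included)
        return n


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the gamma shape given fitted means."""
    r = np.log(y / mu) - y / mu  # each term <= -1, equality iff y == mu
    c = float(np.mean(r))

    def score(log_a: float) -> float:
        a = np.exp(log_a)
        return np.log(a) + 1.0 - digamma(a) + c

    # score is decreasing in a; bracket on log-scale
    lo, hi = -6.0, 12.0
    if score(hi) > 0:
        return float(np.exp(hi))
    if score(lo) < 0:
        return float(np.exp(lo))
    return float(np.exp(brentq(score, lo, hi)))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: np.ndarray) -> float:
    a = shape
    return float(
        np.sum(a * (np.log(a) - np.log(mu)) + (a - 1) * np.log(y) - a * y / mu - gammaln(a))
    )


@dataclass
class HurdleFit:
    """Fitted two-part diurnal model for one animal."""

    pig_id: str
    kind: str
    periods: pd.DataFrame
    included_periods: list[int]
    frame: pd.DataFrame = field(repr=False)
    builder_prob: _DesignBuilder = field(repr=False)
    builder_intake: _DesignBuilder = field(repr=False)
    params_prob: np.ndarray = field(repr=False)
    params_intake: np.ndarray = field(repr=False)
    sigma_by_period: dict[int, float]
    loglik_prob: float
    loglik_intake: float
    prob_constant: float | None = None
    intake_flagged_periods: list[int] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_prob + self.loglik_intake

    @property
    def n_params(self) -> int:
        n_prob = 1 if self.prob_constant is not None else self.builder_prob.n_params
        return n_prob + self.builder_intake.n_params + len(self.sigma_by_period)

    def _pred_frame(self, period_id: int, hours: np.ndarray, day) -> pd.DataFrame:
        hours = np.atleast_1d(np.asarray(hours, dtype=float))
        day = np.broadcast_to(np.asarray(day, dtype=float), hours.shape)
        return pd.DataFrame({"hour": hours % 24.0, "day": day, "period_id": period_id})

    def predict(
        self, period_id: int, hours: np.ndarray, day: float | np.ndarray
    ) -> pd.DataFrame:
        """Fitted probability, positive-intake mean and expected intake."""
        if period_id not in self.included_periods:
            raise ValueError(f"period {period_id} excluded for pig {self.pig_id}")
        pf = self._pred_frame(period_id, hours, day)
        if self.prob_constant is not None:
            prob = np.full(len(pf), self.prob_constant)
        else:
            eta = self.builder_prob.matrix(pf) @ self.params_prob
            prob = 1.0 / (1.0 + np.exp(-eta))
        mu = np.exp(self.builder_intake.matrix(pf) @ self.params_intake)
        pf["prob"] = prob
        pf["mu"] = mu
        pf["predicted_intake"] = prob * mu
        return pf

    def _period_days(self, period_id: int) -> np.ndarray:
        return np.sort(self.frame.loc[self.frame["period_id"] == period_id, "day"].unique())

    def _mean_trend_row(self, builder: _DesignBuilder, period_id: int) -> np.ndarray:
        days = self._period_days(period_id)
        bs = np.asarray(
            patsy.build_design_matrices(
                [builder._bs_info], pd.DataFrame({"day": days})
            )[0]
        )
        return bs.mean(axis=0)

    def predict_detrended(self, period_id: int, hours: np.ndarray) -> pd.DataFrame:
        """Diurnal curves with the day-trend spline held at its period mean.

        This is the comparable-across-periods prediction from which the
        diurnal features are extracted.
        """
        if period_id not in self.included_periods:
            raise ValueError(f"period {period_id} excluded for pig {self.pig_id}")
        hours = np.atleast_1d(np.asarray(hours, dtype=float))
        # any in-range day works: the trend columns are replaced below
        pf = self._pred_frame(period_id, hours, float(self.frame["day"].median()))
        if self.prob_constant is not None:
            prob = np.full(len(pf), self.prob_constant)
        else:
            Xp = self.builder_prob.matrix_mean_trend(
                pf, self._mean_trend_row(self.builder_prob, period_id)
            )
            prob = 1.0 / (1.0 + np.exp(-(Xp @ self.params_prob)))
        Xi = self.builder_intake.matrix_mean_trend(
            pf, self._mean_trend_row(self.builder_intake, period_id)
        )
        mu = np.exp(Xi @ self.params_intake)
        pf["prob"] = prob
        pf["mu"] = mu
        pf["predicted_intake"] = prob * mu
        return pf

    def prob_surface(self, period_id: int, hours: np.ndarray) -> np.ndarray:
        """Fitted eating probability over (day, hour) for the period."""
        days = self._period_days(period_id)
        out = np.empty((len(days), len(np.atleast_1d(hours))))
        for i, d in enumerate(days):
            out[i] = self.predict(period_id, hours, d)["prob"].to_numpy()
        return out


def fit_hurdle(
    series: HourlyIntakeSeries,
    periods: pd.DataFrame,
    kind: str = "full",
    min_days: int = MIN_DAYS_PER_PERIOD,
) -> HurdleFit:
    """Fit the hurdle model on one animal's retained pig-periods.

    Rows from periods with fewer than ``min_days`` available days are
    excluded before fitting.  ``kind`` selects the full model (one
    diurnal smooth per period), ``single_diurnal`` (one shared smooth) or
    ``trend_only`` (no diurnal structure); the latter two are the reduced
    models for likelihood-ratio comparison.
    """
    avail = period_availability(series, periods, min_days=min_days)
    included = avail.loc[avail["included"], "period_id"].astype(int).tolist()
    if not included:
        raise ValueError(f"pig {series.pig_id}: no period with >= {min_days} days")
    frame = series_to_model_frame(series, periods)
    frame = frame[frame["period_id"].isin(included)].reset_index(drop=True)
    if (frame["eat"] > 0).sum() == 0:
        raise ValueError(f"pig {series.pig_id}: no positive intakes")

    builder_p = _DesignBuilder(frame, kind, included)
    builder_i = _DesignBuilder(frame, kind, included)

    # binary part
    y = frame["eat"].to_numpy()
    prob_constant = None
    if y.min() == y.max():
        # degenerate animal (eats every hour, or never): constant fit
        n = len(y)
        prob_constant = (y.sum() + 0.5) / (n + 1.0)
        params_p = np.zeros(builder_p.n_params)
        ll_p = float(n * (y.mean() * np.log(prob_constant) + (1 - y.mean()) * np.log(1 - prob_constant)))
    else:
        Xp = builder_p.matrix(frame)
        res_p = sm.GLM(y, Xp, family=sm.families.Binomial()).fit(maxiter=200)
        if not res_p.converged:
            raise RuntimeError(f"pig {series.pig_id}: probability part did not converge")
        params_p = np.asarray(res_p.params)
        ll_p = float(res_p.llf)

    # positive part: gamma with log link, per-period shape
    pos = frame[frame["intake_g"] > 0].reset_index(drop=True)
    Xi = builder_i.matrix(pos)
    ypos = pos["intake_g"].to_numpy()
    pid = pos["period_id"].to_numpy()
    flagged = [p for p in included if np.sum(pid == p) == 0]
    weights = np.ones(len(ypos))
    shapes: dict[int, float] = {p: 1.0 for p in included}
    res_i = None
    for _ in range(3):
        res_i = sm.GLM(
            ypos, Xi, family=sm.families.Gamma(link=sm.families.links.Log()),
            var_weights=weights,
        ).fit(maxiter=200)
        mu = np.asarray(res_i.mu)
        for p in included:
            sel = pid == p
            if sel.sum() >= 2:
                shapes[p] = _gamma_shape_mle(ypos[sel], mu[sel])
        weights = np.array([shapes[p] for p in pid])
    params_i = np.asarray(res_i.params)
    shape_vec = np.array([shapes[p] for p in pid])
    ll_i = _gamma_loglik(ypos, np.asarray(res_i.mu), shape_vec)

    return HurdleFit(
        pig_id=series.pig_id,
        kind=kind,
        periods=periods,
        included_periods=included,
        frame=frame,
        builder_prob=builder_p,
        builder_intake=builder_i,
        params_prob=params_p,
        params_intake=params_i,
        sigma_by_period=shapes,
        loglik_prob=ll_p,
        loglik_intake=ll_i,
        prob_constant=prob_constant,
        intake_flagged_periods=flagged,
    )


@dataclass(frozen=True)
class LRResult:
    statistic: float
    df: int
    pvalue: float
    full_kind: str
    reduced_kind: str


def lr_compare(full: HurdleFit, reduced: HurdleFit) -> LRResult:
    """Likelihood-ratio chi-square test of the full hurdle model against a
    reduced variant fitted on the same rows."""
    from scipy.stats import chi2

    if full.pig_id != reduced.pig_id or len(full.frame) != len(reduced.frame):
        raise ValueError("models must be fitted on identical data")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return LRResult(stat, df, p, full.kind, reduced.kind)
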