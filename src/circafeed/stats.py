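"""Consistency statistics on the feature table.

Each feature is modelled across animal-periods with a linear mixed model:
period as a fixed factor, pen and pig as random intercepts, and an AR(1)
correlation between an animal's residuals in consecutive periods
(excluded periods act as true time gaps, correlation rho^gap).  The model
is fitted by REML with the pen/pig/residual variances and the AR
parameter profiled out numerically; pens are independent, so the
likelihood factorises into pen blocks.

From the fit come: a Wald chi-square test for the period effect with
Tukey-adjusted pairwise contrasts and a compact letter display;
intraclass correlations for pen and pig (each variance component over
the total, the residual entering through the diagonal of the AR(1)
covariance); and, per period, Spearman rank-correlation matrices over
all features with pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular
from scipy.stats import chi2, shapiro, studentized_range

__all__ = [
    "TransformSpec",
    "DEFAULT_TRANSFORMS",
    "apply_transforms",
    "transform_and_check",
    "PeriodModel",
    "fit_period_model",
    "PeriodEffectTest",
    "test_period_effect",
    "ICCReport",
    "compute_icc",
    "spearman_matrix",
    "strength_label",
]


# ---------------------------------------------------------------------------
# transforms and normality gate

@dataclass(frozen=True)
class TransformSpec:
    """Per-feature variance-stabilising transforms.

    Values are 'identity', 'sqrt', 'log' or ('const_minus_sqrt', c)
    meaning c - sqrt(x).  ``shapiro_W_threshold`` flags features whose
    model residuals fall below the stated Shapiro-Wilk W.
    """

    transforms: dict = field(default_factory=dict)
    shapiro_W_threshold: float = 0.9


#: transforms used for the canonical feature set: square root for the
#: low extremes, log for the peak quantities, and a reflected square
#: root for peak timing (constant 24 = the hour-scale maximum).
DEFAULT_TRANSFORMS = TransformSpec(
    transforms={
        "peak_time_h": ("const_minus_sqrt", 24.0),
        "peak_height": "log",
        "peak_width": "log",
        "lowest_intake": "sqrt",
        "min_prob_eat": "sqrt",
        "night_prop": "identity",
        "max_prob_eat": "identity",
    }
)


def _apply_one(x: pd.Series, how) -> pd.Series:
    if how == "identity":
        return x
    if how == "sqrt":
        if (x.dropna() < 0).any():
            bad = x.index[x < 0].tolist()
            raise ValueError(f"sqrt transform on negative values at rows {bad}")
        return np.sqrt(x)
    if how == "log":
        if (x.dropna() <= 0).any():
            bad = x.index[x <= 0].tolist()
            raise ValueError(f"log transform on non-positive values at rows {bad}")
        return np.log(x)
    if isinstance(how, (tuple, list)) and how[0] == "const_minus_sqrt":
        c = float(how[1])
        if (x.dropna() < 0).any():
            bad = x.index[x < 0].tolist()
            raise ValueError(f"const_minus_sqrt on negative values at rows {bad}")
        return c - np.sqrt(x)
    raise ValueError(f"unknown transform {how!r}")


def apply_transforms(features: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    out = features.copy()
    for col, how in spec.transforms.items():
        if col in out.columns:
            out[col] = _apply_one(out[col], how)
    return out


# ---------------------------------------------------------------------------
# mixed model with AR(1) residuals, fitted by REML on pen blocks

@dataclass
class PeriodModel:
    """REML fit of one feature: period fixed effects, pen + pig random
    intercepts, AR(1) residuals within pig across periods."""

    feature: str
    period_levels: list
    beta: np.ndarray
    cov_beta: np.ndarray
    var_pen: float
    var_pig: float
    var_resid: float
    rho: float
    n_obs: int
    reml_loglik: float
    converged: bool
    boundary: bool
    residuals: np.ndarray = field(repr=False)


def _pen_blocks(df: pd.DataFrame, value_col: str):
    """Per-pen (y, X, pig labels, period positions) in a fixed order."""
    period_levels = sorted(df["period"].unique())
    pos = {p: i for i, p in enumerate(period_levels)}
    blocks = []
    for pen, g in df.groupby("pen", sort=True):
        g = g.sort_values(["pig", "period"])
        y = g[value_col].to_numpy(dtype=float)
        t = np.array([pos[p] for p in g["period"]], dtype=float)
        X = np.ones((len(g), len(period_levels)))
        for j, p in enumerate(period_levels[1:], start=1):
            X[:, j] = (g["period"] == p).to_numpy(dtype=float)
        pigs = g["pig"].to_numpy()
        blocks.append((y, X, pigs, t))
    return blocks, period_levels


def _block_cov(pigs: np.ndarray, t: np.ndarray, vp: float, vg: float, ve: float, rho: float) -> np.ndarray:
    n = len(pigs)
    same_pig = pigs[:, None] == pigs[None, :]
    V = np.full((n, n), vp)
    V += np.where(same_pig, vg, 0.0)
    lag = np.abs(t[:, None] - t[None, :])
    V += np.where(same_pig, ve * rho**lag, 0.0)
    # tiny ridge keeps the Cholesky stable when components collapse to 0
    V[np.diag_indices(n)] += 1e-8 * (vp + vg + ve) + 1e-12
    return V


def _reml_nll(theta: np.ndarray, blocks) -> float:
    vp, vg, ve = np.exp(theta[:3])
    rho = np.tanh(theta[3])
    p = blocks[0][1].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for y, X, pigs, t in blocks:
        V = _block_cov(pigs, t, vp, vg, ve, rho)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        wy = solve_triangular(L, y, lower=True)
        wX = solve_triangular(L, X, lower=True)
        XtViX += wX.T @ wX
        XtViy += wX.T @ wy
        ytViy += wy @ wy
    sign, logdet_xtx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - beta @ XtViy
    return 0.5 * (logdet + logdet_xtx + quad)


def fit_period_model(
    df: pd.DataFrame, value_col: str = "value", feature: str = ""
) -> PeriodModel:
    """Fit the period mixed model to one feature column.

    ``df`` needs columns pen, pig, period and the value column; rows with
    NaN values are dropped.  Requires >= 2 periods, >= 2 pens and >= 2
    pigs per pen.
    """
    df = df.dropna(subset=[value_col])
    if df["period"].nunique() < 2:
        raise ValueError("need >= 2 periods")
    if df["pen"].nunique() < 2:
        raise ValueError("need >= 2 pens")
    if df.groupby("pen")["pig"].nunique().min() < 2:
        raise ValueError("need >= 2 pigs per pen")
    blocks, period_levels = _pen_blocks(df, value_col)

    vy = float(np.var(df[value_col], ddof=1))
    x0 = np.array([np.log(vy / 4 + 1e-10), np.log(vy / 2 + 1e-10),
                   np.log(vy / 2 + 1e-10), np.arctanh(0.2)])
    bounds = [(-14.0, 14.0)] * 3 + [(-2.5, 2.5)]
    res = optimize.minimize(
        _reml_nll, x0, args=(blocks,), method="L-BFGS-B", bounds=bounds
    )
    vp, vg, ve = np.exp(res.x[:3])
    rho = float(np.tanh(res.x[3]))
    boundary = bool(np.any(res.x[:3] <= -13.5))

    # GLS estimates and conditional residuals at the optimum
    p = len(period_levels)
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    for y, X, pigs, t in blocks:
        V = _block_cov(pigs, t, vp, vg, ve, rho)
        L = np.linalg.cholesky(V)
        wy = solve_triangular(L, y, lower=True)
        wX = solve_triangular(L, X, lower=True)
        XtViX += wX.T @ wX
        XtViy += wX.T @ wy
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ XtViy

    resids = []
    for y, X, pigs, t in blocks:
        V = _block_cov(pigs, t, vp, vg, ve, rho)
        r = y - X @ beta
        Vir = np.linalg.solve(V, r)
        b_pen = vp * np.sum(Vir)
        cond = r - b_pen
        for pig in np.unique(pigs):
            sel = pigs == pig
            cond[sel] -= vg * np.sum(Vir[sel])
        resids.append(cond)
    return PeriodModel(
        feature=feature,
        period_levels=period_levels,
        beta=beta,
        cov_beta=cov_beta,
        var_pen=float(vp),
        var_pig=float(vg),
        var_resid=float(ve),
        rho=rho,
        n_obs=len(df),
        reml_loglik=-float(res.fun),
        converged=bool(res.success),
        boundary=boundary,
        residuals=np.concatenate(resids),
    )


def transform_and_check(
    features: pd.DataFrame,
    spec: TransformSpec = DEFAULT_TRANSFORMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-feature transforms and gate on residual normality.

    Fits the period mixed model per transformed feature and reports the
    Shapiro-Wilk W of its conditional residuals; W below the threshold
    flags the feature.  Returns (transformed table, normality report).
    """
    out = apply_transforms(features, spec)
    long = _to_model_long(out)
    rows = []
    for col in spec.transforms:
        if col not in features.columns:
            continue
        sub = long[long["feature"] == col]
        try:
            model = fit_period_model(sub, feature=col)
            W = float(shapiro(model.residuals).statistic)
        except ValueError:
            W = np.nan
        rows.append(
            {
                "feature": col,
                "shapiro_W": W,
                "ok": bool(W >= spec.shapiro_W_threshold) if np.isfinite(W) else False,
            }
        )
    return out, pd.DataFrame(rows)


def _to_model_long(features: pd.DataFrame) -> pd.DataFrame:
    """Feature table -> long frame with pen/pig/period columns."""
    df = features.copy()
    if "pen_id" not in df.columns:
        raise ValueError("feature table needs a pen_id column for the mixed model")
    value_cols = [
        c for c in df.columns if c not in ("pig_id", "pen_id", "period_id")
    ]
    long = df.melt(
        id_vars=["pig_id", "pen_id", "period_id"],
        value_vars=value_cols,
        var_name="feature",
        value_name="value",
    )
    return long.rename(columns={"pig_id": "pig", "pen_id": "pen", "period_id": "period"})


# ---------------------------------------------------------------------------
# period effect: Wald chi-square + Tukey pairwise contrasts

@dataclass
class PeriodEffectTest:
    chi2: float
    df: int
    pvalue: float
    pairwise: pd.DataFrame | None
    letters: dict | None


def test_period_effect(model: PeriodModel, alpha: float = 0.05) -> PeriodEffectTest:
    """Wald chi-square for the period factor; if significant, Tukey-style
    pairwise contrasts (studentized-range adjustment) with a compact
    letter display."""
    k = len(model.period_levels)
    b = model.beta[1:]
    C = model.cov_beta[1:, 1:]
    stat = float(b @ np.linalg.solve(C, b))
    df = k - 1
    p = float(chi2.sf(stat, df))
    if p >= alpha:
        return PeriodEffectTest(stat, df, p, None, None)

    # cell means and their covariance (treatment parameterisation)
    A = np.zeros((k, k))
    A[:, 0] = 1.0
    for i in range(1, k):
        A[i, i] = 1.0
    means = A @ model.beta
    covm = A @ model.cov_beta @ A.T
    df_resid = max(model.n_obs - k, 2)
    rows = []
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(covm[i, i] + covm[j, j] - 2 * covm[i, j])
            q = abs(diff) / se * np.sqrt(2.0)
            padj = float(studentized_range.sf(q, k, df_resid))
            sig[i, j] = sig[j, i] = padj < alpha
            rows.append(
                {
                    "period_a": model.period_levels[i],
                    "period_b": model.period_levels[j],
                    "estimate": float(diff),
                    "se": float(se),
                    "p_adj": padj,
                }
            )
    letters = _letter_display(means, sig, model.period_levels)
    return PeriodEffectTest(stat, df, p, pd.DataFrame(rows), letters)


def _letter_display(means: np.ndarray, sig: np.ndarray, levels: list) -> dict:
    """Compact letters from maximal windows of mutually non-significant
    groups in mean order (exact when non-significance is contiguous in
    the mean ordering, the usual case for a monotone period trend)."""
    order = np.argsort(means)
    k = len(order)
    windows = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not any(
            sig[order[a], order[j + 1]] for a in range(i, j + 1)
        ):
            j += 1
        windows.append(set(order[i : j + 1].tolist()))
        i += 1
    # keep only maximal windows
    maximal = [w for w in windows if not any(w < o for o in windows)]
    seen = []
    uniq = []
    for w in maximal:
        if w not in seen:
            seen.append(w)
            uniq.append(w)
    letters: dict = {levels[i]: "" for i in range(k)}
    for idx, w in enumerate(uniq):
        ch = chr(ord("a") + idx)
        for g in w:
            letters[levels[g]] += ch
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


# ---------------------------------------------------------------------------
# ICC and correlation matrices

def strength_label(v: float) -> str:
    """Weak / moderate / strong bands at |0.4| and |0.6|."""
    a = abs(v)
    if a >= 0.6:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


@dataclass
class ICCReport:
    feature: str
    var_pig: float
    var_pen: float
    var_resid: float
    icc_pig: float
    icc_pen: float
    label_pig: str
    label_pen: str


def compute_icc(model: PeriodModel) -> ICCReport:
    """Variance shares of pig and pen over the total (pig + pen + AR(1)
    diagonal), labelled by the weak/moderate/strong bands."""
    total = model.var_pig + model.var_pen + model.var_resid
    if total <= 0:
        raise ValueError("all variance components are zero; ICC undefined")
    icc_pig = model.var_pig / total
    icc_pen = model.var_pen / total
    return ICCReport(
        feature=model.feature,
        var_pig=model.var_pig,
        var_pen=model.var_pen,
        var_resid=model.var_resid,
        icc_pig=float(icc_pig),
        icc_pen=float(icc_pen),
        label_pig=strength_label(icc_pig),
        label_pen=strength_label(icc_pen),
    )


def spearman_matrix(
    features: pd.DataFrame,
    period_id: int | None = None,
    id_cols: tuple = ("pig_id", "pen_id", "period_id"),
    min_rows: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlations between all feature columns.

    Pairwise-complete observations, average ranks for ties.  Constant
    columns give NaN for their pairs.  ``period_id`` restricts to one
    period.
    """
    df = features
    if period_id is not None:
        df = df[df["period_id"] == period_id]
    cols = [c for c in df.columns if c not in id_cols]
    sub = df[cols]
    if len(sub.dropna(how="all")) < min_rows:
        raise ValueError(f"fewer than {min_rows} rows available")
    mat = sub.corr(method="spearman", min_periods=min_rows)
    np.fill_diagonal(mat.values, 1.0)
    const = [c for c in cols if sub[c].dropna().nunique() <= 1]
    for c in const:
        mat.loc[c, :] = np.nan
        mat.loc[:, c] = np.nan
    return mat
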