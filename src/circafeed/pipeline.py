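"""End-to-end orchestration: data -> detrend -> wavelet -> hurdle ->
features -> statistics, with a manifest for reproducibility.

Every stage writes tidy CSV/JSON artifacts into the output directory, so
a run can be inspected or resumed per stage.  A fixed config plus seed
determines every numeric output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .series import HourlyIntakeSeries, series_to_frame
from . import synth, ingest, detrend, wavelet, hurdle_gam, features as feat
from . import stats as fstats

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """All stage parameters plus toggles; YAML-loadable."""

    seed: int = 0
    outdir: str = "circafeed_out"
    # data source: 'synth' or 'visits'
    source: str = "synth"
    visits_path: str | None = None
    events_path: str | None = None
    start_date: str = "2020-12-15"
    # synth stage
    n_pens: int = 2
    pigs_per_pen: int = 4
    n_days: int = 42
    missing_day_prob: float = 0.03
    # cleaning
    rules: dict = field(default_factory=dict)
    # detrend
    loess_span: float = 0.75
    loess_degree: int = 1
    amplitude_window_days: int = 7
    # wavelet
    do_wavelet: bool = True
    n_sim: int = 1000
    alpha: float = 0.05
    voices: int = 20
    period_lo: float = 8.0
    period_hi: float = 48.0
    band: tuple = (23.5, 24.5)
    # hurdle
    period_len: int = 14
    min_days_per_period: int = 7
    do_lr_tests: bool = False
    # stats
    do_stats: bool = True
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, pig_id: str | None, cause: Exception):
        self.stage = stage
        self.pig_id = pig_id
        super().__init__(f"stage {stage!r}" + (f" (pig {pig_id})" if pig_id else "") + f": {cause}")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _get_cohort(config: PipelineConfig) -> tuple[list[HourlyIntakeSeries], synth.CohortSpec | None]:
    if config.source == "synth":
        spec = synth.CohortSpec(
            n_pens=config.n_pens,
            pigs_per_pen=config.pigs_per_pen,
            n_days=config.n_days,
            missing_day_prob=config.missing_day_prob,
            start_date=config.start_date,
            seed=config.seed,
        )
        return synth.simulate_cohort(spec), spec
    if config.source == "visits":
        if not config.visits_path:
            raise ValueError("source 'visits' requires visits_path")
        visits, _ = ingest.parse_visits(config.visits_path)
        rules = ingest.CleaningRules(**config.rules)
        cleaned, report = ingest.clean_visits(visits, rules)
        first = cleaned["entry_ts"].min().normalize()
        last = cleaned["exit_ts"].max().normalize()
        n_days = (last - first).days + 1
        cohort = ingest.aggregate_hourly(
            cleaned, first, n_days, removed_pig_days=report.removed_pig_days
        )
        if config.events_path:
            ev = ingest.WelfareEvents.from_frame(pd.read_csv(config.events_path))
            cohort = [ingest.filter_pig_days(s, ev)[0] for s in cohort]
        return cohort, None
    raise ValueError(f"unknown source {config.source!r}")


def run_all(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- data
    try:
        cohort, spec = _get_cohort(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("data", None, e) from e
    series_to_frame(cohort).to_csv(out / "hourly.csv", index=False)

    first_day = int(min(s.day_index.min() for s in cohort))
    last_day = int(max(s.day_index.max() for s in cohort))
    periods = hurdle_gam.assign_periods(first_day, last_day, config.period_len)
    periods.to_csv(out / "periods.csv", index=False)

    # ---- wavelet branch
    summary_period = None
    if config.do_wavelet:
        calls_frames = []
        rng_seed = np.random.SeedSequence(config.seed)
        child_seeds = rng_seed.spawn(len(cohort))
        for s, cs in zip(cohort, child_seeds):
            try:
                det = detrend.prepare_series(
                    s, span=config.loess_span, window_days=config.amplitude_window_days
                )
                spct = wavelet.morlet_cwt(
                    det, config.period_lo, config.period_hi, config.voices
                )
                spct.pig_id = s.pig_id
                spct = wavelet.surrogate_pvalues(
                    spct, det, n_sim=config.n_sim, seed=cs
                )
                calls_frames.append(
                    wavelet.call_circadian_days(spct, tuple(config.band), config.alpha)
                )
            except Exception as e:  # noqa: BLE001
                raise StageError("wavelet", s.pig_id, e) from e
        calls = pd.concat(calls_frames, ignore_index=True)
        calls.to_csv(out / "circadian_calls.csv", index=False)
        summary_month = wavelet.summarise_rhythm(calls, grouping="month")
        summary_month.to_csv(out / "rhythm_by_month.csv", index=False)
        summary_period = wavelet.summarise_rhythm(
            calls, grouping="period", periods=periods
        )
        summary_period.to_csv(out / "rhythm_by_period.csv", index=False)

    # ---- hurdle fits and features
    rows = []
    fit_meta = {}
    for s in cohort:
        try:
            fit = hurdle_gam.fit_hurdle(
                s, periods, min_days=config.min_days_per_period
            )
            f = feat.features_for_fit(fit)
            f.insert(1, "pen_id", s.pen_id)
            rows.append(f)
            fit_meta[s.pig_id] = {
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "sigma_by_period": {str(k): v for k, v in fit.sigma_by_period.items()},
                "included_periods": fit.included_periods,
            }
            if config.do_lr_tests:
                red1 = hurdle_gam.fit_hurdle(
                    s, periods, kind="trend_only", min_days=config.min_days_per_period
                )
                red2 = hurdle_gam.fit_hurdle(
                    s, periods, kind="single_diurnal", min_days=config.min_days_per_period
                )
                fit_meta[s.pig_id]["lr_vs_trend_only"] = asdict(
                    hurdle_gam.lr_compare(fit, red1)
                )
                fit_meta[s.pig_id]["lr_vs_single_diurnal"] = asdict(
                    hurdle_gam.lr_compare(fit, red2)
                )
        except Exception as e:  # noqa: BLE001
            raise StageError("hurdle_gam", s.pig_id, e) from e
    features = pd.concat(rows, ignore_index=True)
    if summary_period is not None:
        features = feat.join_circadian(features, summary_period)
    features.to_csv(out / "features.csv", index=False)
    (out / "fits.json").write_text(json.dumps(fit_meta, indent=1))

    # ---- statistics
    if config.do_stats:
        try:
            stats_out = run_stats(features)
            (out / "stats.json").write_text(json.dumps(stats_out, indent=1))
        except Exception as e:  # noqa: BLE001
            raise StageError("stats", None, e) from e

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "n_pigs": len(cohort),
        "n_feature_rows": len(features),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def run_stats(features: pd.DataFrame) -> dict:
    """Mixed-model, ICC and correlation summaries of a feature table."""
    spec = fstats.DEFAULT_TRANSFORMS
    transformed, norm_report = fstats.transform_and_check(features, spec)
    long = fstats._to_model_long(transformed)
    out: dict = {"normality": norm_report.to_dict(orient="records"), "features": {}}
    for col in spec.transforms:
        if col not in features.columns:
            continue
        sub = long[long["feature"] == col]
        try:
            model = fstats.fit_period_model(sub, feature=col)
        except ValueError as e:
            out["features"][col] = {"error": str(e)}
            continue
        eff = fstats.test_period_effect(model)
        icc = fstats.compute_icc(model)
        out["features"][col] = {
            "chi2": eff.chi2,
            "df": eff.df,
            "p": eff.pvalue,
            "letters": {str(k): v for k, v in (eff.letters or {}).items()},
            "icc_pig": icc.icc_pig,
            "icc_pen": icc.icc_pen,
            "icc_pig_label": icc.label_pig,
            "icc_pen_label": icc.label_pen,
            "var_pig": icc.var_pig,
            "var_pen": icc.var_pen,
            "var_resid": icc.var_resid,
            "rho": model.rho,
        }
    corr = {}
    for pid in sorted(features["period_id"].unique()):
        try:
            mat = fstats.spearman_matrix(features, period_id=int(pid))
            corr[str(int(pid))] = json.loads(mat.to_json())
        except ValueError:
            continue
    out["spearman_by_period"] = corr
    return out
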