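"""End-to-end orchestration: simulate/load -> preprocess -> quantiles ->
models -> contrasts -> trend -> figures, with a reproducible manifest."""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    anova_table,
    contrasts_vs_zero,
    delta_model_spec,
    emm,
    fit_lmm,
    pairwise_tukey,
    rt_model_spec,
    stepwise_reduce,
)
from .plots import plot_cdf, plot_delta
from .preprocess import preprocess, read_trials
from .quantiles import DEFAULT_PROBS, build_cdf_dataset, build_delta_dataset, vincentize
from .synth import DeltaProfile, ExGaussian, SimConfig, simulate_cohort
from .trend import compare_trends, fit_trend_model

__all__ = ["PipelineConfig", "run_pipeline", "classify_effects"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything that determines a run.

    Either ``input_csv`` (trial-level data) or ``sim`` (a synthetic-cohort
    configuration) must be set; a single top-level ``seed`` drives all
    randomness.
    """

    input_csv: str | None = None
    sim: SimConfig | None = None
    probs: tuple[float, ...] = DEFAULT_PROBS
    rt_low: float = 200.0
    rt_high: float = 1300.0
    trim_mode: str = "trimmed"
    nonresponse_threshold: float = 0.5
    min_trials_per_cell: int = 10
    alpha: float = 0.05
    stepwise: bool = True
    seed: int = 0
    out_dir: str = "run"
    figure_format: str = "png"
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.sim is not None:
            sim = d["sim"]
            sim["baselines"] = {
                k: asdict(v) for k, v in self.sim.baselines.items()
            }
            sim["profiles"] = {k: asdict(v) for k, v in self.sim.profiles.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            sim["baselines"] = {
                k: ExGaussian(**v) for k, v in sim.get("baselines", {}).items()
            }
            sim["profiles"] = {
                k: DeltaProfile(**v) for k, v in sim.get("profiles", {}).items()
            }
            for key in ("target_types", "contamination"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if "probs" in d:
            d["probs"] = tuple(d["probs"])
        return cls(**d)


def classify_effects(vs_zero: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label each target x probability delta as SCE (positive, significant),
    RCE (negative, significant) or none, from the vs-zero contrasts."""
    out = vs_zero.copy()
    sig = out["p_adj"] < alpha
    out["effect"] = np.where(
        sig & (out["estimate"] > 0), "SCE", np.where(sig, "RCE", "none")
    )
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _model_factors(fit) -> set[str]:
    from .design import Factor

    return {
        name
        for name, var in fit.design.variables.items()
        if isinstance(var, Factor) and var.ncols > 0
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and persist all tables, figures and a manifest.

    Returns the run directory.  Any stage failure raises with the stage
    name; outputs written so far stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    timings: dict[str, float] = {}
    stage = "setup"

    def tick(name: str, t0: float) -> float:
        timings[name] = round(time.perf_counter() - t0, 3)
        return time.perf_counter()

    try:
        t0 = time.perf_counter()
        stage = "input"
        if config.input_csv is not None:
            trials = read_trials(config.input_csv)
        elif config.sim is not None:
            sim = config.sim
            if config.seed is not None:
                sim = sim.with_(seed=config.seed)
            trials = simulate_cohort(sim)
            trials.to_csv(out / "trials.csv", index=False, float_format="%.6f")
        else:
            raise ValueError("config needs input_csv or sim")
        t0 = tick(stage, t0)

        stage = "preprocess"
        retained, report, excluded = preprocess(
            trials,
            low=config.rt_low,
            high=config.rt_high,
            mode=config.trim_mode,
            nonresponse_threshold=config.nonresponse_threshold,
        )
        report.to_tsv(out / "removal_report.tsv")
        _write(report.by_cell, out / "removal_by_cell.tsv")
        t0 = tick(stage, t0)

        stage = "quantiles"
        cdf = build_cdf_dataset(retained, config.probs, config.min_trials_per_cell)
        delta = build_delta_dataset(cdf)
        _write(cdf, out / "cdf_dataset.tsv")
        _write(delta, out / "delta_dataset.tsv")
        _write(vincentize(delta, by=("target_type",)), out / "vincentized_delta.tsv")
        t0 = tick(stage, t0)

        stage = "rt_model"
        rt_spec = rt_model_spec()
        if config.stepwise:
            rt_spec, rt_log = stepwise_reduce(rt_spec, cdf, config.alpha)
        else:
            rt_log = []
        rt_fit = fit_lmm(cdf, rt_spec)
        _write(rt_fit.coef_table(), out / "rt_coefficients.tsv")
        _write(rt_fit.varcomp_table(), out / "rt_varcomps.tsv")
        _write(anova_table(rt_fit), out / "rt_anova.tsv")
        rt_factors = _model_factors(rt_fit)
        rt_emm = emm(rt_fit, tuple(f for f in ("target_type", "congruency") if f in rt_factors))
        _write(rt_emm.table, out / "rt_emm_target_congruency.tsv")
        if {"target_type", "congruency"} <= set(rt_emm.factors):
            _write(
                pairwise_tukey(rt_emm, "target_type", by="congruency"),
                out / "rt_contrasts_target_by_congruency.tsv",
            )
            _write(
                pairwise_tukey(rt_emm, "congruency", by="target_type"),
                out / "rt_contrasts_congruency_by_target.tsv",
            )
        rt_emm_q = emm(
            rt_fit,
            tuple(f for f in ("target_type", "congruency", "prob") if f in rt_factors),
        )
        _write(rt_emm_q.table, out / "rt_emm_by_quantile.tsv")
        t0 = tick(stage, t0)

        stage = "delta_model"
        d_spec = delta_model_spec()
        if config.stepwise:
            d_spec, d_log = stepwise_reduce(d_spec, delta, config.alpha)
        else:
            d_log = []
        d_fit = fit_lmm(delta, d_spec)
        _write(d_fit.coef_table(), out / "delta_coefficients.tsv")
        _write(d_fit.varcomp_table(), out / "delta_varcomps.tsv")
        _write(anova_table(d_fit), out / "delta_anova.tsv")
        d_factors = _model_factors(d_fit)
        d_emm_t = emm(d_fit, tuple(f for f in ("target_type",) if f in d_factors))
        _write(d_emm_t.table, out / "delta_emm_target.tsv")
        d_emm_tq = emm(
            d_fit, tuple(f for f in ("target_type", "prob") if f in d_factors)
        )
        _write(d_emm_tq.table, out / "delta_emm_target_quantile.tsv")
        vs0 = contrasts_vs_zero(d_emm_tq, adjust="bonferroni")
        vs0 = classify_effects(vs0, config.alpha)
        _write(vs0, out / "delta_vs_zero.tsv")
        t0 = tick(stage, t0)

        stage = "trend_model"
        trend = fit_trend_model(delta)
        trend_res = compare_trends(trend)
        _write(trend.fit.varcomp_table(), out / "trend_varcomps.tsv")
        _write(trend_res.coefficients, out / "trend_coefficients.tsv")
        _write(trend_res.differences, out / "trend_differences.tsv")
        t0 = tick(stage, t0)

        stage = "figures"
        fmt = config.figure_format
        cdf_emm = rt_emm_q.table
        if {"target_type", "congruency", "prob"} <= set(cdf_emm.columns):
            plot_cdf(cdf_emm, out / f"cdf_plot.{fmt}")
        if {"target_type", "prob"} <= set(d_emm_tq.table.columns) and "prob" in cdf_emm:
            dplot = d_emm_tq.table.rename(columns={"estimate": "delta"}).copy()
            rt_mean = (
                cdf_emm.groupby(["target_type", "prob"], observed=True)["estimate"]
                .mean()
                .rename("mean_rt")
                .reset_index()
            )
            dplot = dplot.merge(rt_mean, on=["target_type", "prob"])
            plot_delta(dplot, out / f"delta_plot.{fmt}")
        t0 = tick(stage, t0)

        stage = "manifest"
        manifest = {
            "package": "stroopdelta",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "probs": list(config.probs),
            "df_method": "satterthwaite",
            "stepwise_rt": rt_log,
            "stepwise_delta": d_log,
            "excluded_participants": [list(e) for e in excluded],
            "timings_s": timings,
        }
        config.to_yaml(out / "config.yaml")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
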