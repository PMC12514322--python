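"""Deterministic CDF and delta-plot figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_cdf", "plot_delta"]

_TARGET_ORDER = ["face", "eyes", "arrows"]
_COLORS = {"face": "#c0392b", "eyes": "#2980b9", "arrows": "#27ae60"}
_LINESTYLE = {"congruent": "-", "incongruent": "--"}


def _ordered_targets(values) -> list[str]:
    seen = list(dict.fromkeys(values))
    return [t for t in _TARGET_ORDER if t in seen] + [
        t for t in seen if t not in _TARGET_ORDER
    ]


def plot_cdf(emm_table: pd.DataFrame, path) -> Path:
    """CDF plot: EMM-RT against quantile probability, one polyline per
    target x congruency, with CI bars.  ``emm_table`` needs columns
    target_type, congruency, prob, estimate, ci_low, ci_high."""
    if len(emm_table) == 0:
        raise ValueError("empty EMM table")
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    tab = emm_table.copy()
    tab["prob"] = tab["prob"].astype(float)
    for target in _ordered_targets(tab["target_type"]):
        for cong, sub in tab[tab["target_type"] == target].groupby(
            "congruency", sort=True
        ):
            sub = sub.sort_values("prob")
            err = [sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]]
            ax.errorbar(
                sub["prob"],
                sub["estimate"],
                yerr=err,
                marker="o",
                ms=4,
                capsize=3,
                color=_COLORS.get(target, "black"),
                linestyle=_LINESTYLE.get(cong, "-"),
                label=f"{target} {cong}",
            )
    ax.set_xlabel("quantile probability")
    ax.set_ylabel("EMM-RT (ms)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_delta(delta_table: pd.DataFrame, path) -> Path:
    """Delta plot: EMM-delta (or vincentized delta) against mean RT, one
    polyline per target, CI bars where available.  Needs columns
    target_type, mean_rt, delta (+ optional ci_low / ci_high)."""
    if len(delta_table) == 0:
        raise ValueError("empty delta table")
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    has_ci = {"ci_low", "ci_high"}.issubset(delta_table.columns)
    for target in _ordered_targets(delta_table["target_type"]):
        sub = delta_table[delta_table["target_type"] == target].sort_values("mean_rt")
        yerr = (
            [sub["delta"] - sub["ci_low"], sub["ci_high"] - sub["delta"]]
            if has_ci
            else None
        )
        ax.errorbar(
            sub["mean_rt"],
            sub["delta"],
            yerr=yerr,
            marker="o",
            ms=4,
            capsize=3,
            color=_COLORS.get(target, "black"),
            label=target,
        )
    ax.axhline(0.0, color="gray", lw=0.8, zorder=0)
    ax.set_xlabel("mean RT (ms)")
    ax.set_ylabel("delta = incongruent - congruent (ms)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
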