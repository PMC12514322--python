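"""Per-participant RT quantiles, delta functions and quantile averaging.

The sample quantile estimator is Hyndman & Fan's Type 8 (median-unbiased
interpolation): with order statistics x_(1) <= ... <= x_(n) and
h = (n + 1/3) p + 1/3 clamped to [1, n],

    Q(p) = x_(floor(h)) + (h - floor(h)) * (x_(floor(h)+1) - x_(floor(h))).

The delta function at each probability is the incongruent minus the
congruent quantile of the same participant; group-level curves are
obtained by vincentization, i.e. averaging participant-level quantiles
(or deltas) across participants.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PROBS",
    "QUARTILE_PROBS",
    "DECILE_PROBS",
    "hf_quantile8",
    "build_cdf_dataset",
    "build_delta_dataset",
    "vincentize",
    "MIN_TRIALS_PER_CELL",
]

DEFAULT_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)
QUARTILE_PROBS = (0.125, 0.375, 0.625, 0.875)
DECILE_PROBS = tuple(np.round(np.arange(0.05, 1.0, 0.10), 2))

#: Minimum retained trials per participant x target x congruency cell for
#: that cell to enter the CDF dataset; smaller cells are skipped with a
#: warning (quantile estimates from tiny samples are too noisy to average).
MIN_TRIALS_PER_CELL = 10


def hf_quantile8(sample: Sequence[float] | np.ndarray, p) -> float | np.ndarray:
    """Hyndman-Fan Type-8 sample quantile(s) of ``sample`` at ``p``.

    ``sample`` need not be sorted; ``p`` may be a scalar or array in (0,1).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("cannot compute quantiles of an empty sample")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    h = (n + 1.0 / 3.0) * p_arr + 1.0 / 3.0
    h = np.clip(h, 1.0, float(n))
    lo = np.floor(h).astype(int)  # 1-based
    hi = np.minimum(lo + 1, n)
    frac = h - lo
    out = x[lo - 1] + frac * (x[hi - 1] - x[lo - 1])
    return float(out[0]) if np.isscalar(p) or np.ndim(p) == 0 else out


_CELL_KEY = ["study_id", "participant_id", "target_type", "congruency"]


def build_cdf_dataset(
    table: pd.DataFrame,
    probs: Iterable[float] = DEFAULT_PROBS,
    min_trials: int = MIN_TRIALS_PER_CELL,
) -> pd.DataFrame:
    """Per-participant condition quantiles: the CDF dataset.

    One row per participant x target x congruency x probability with the
    Type-8 quantile of that cell's retained RTs.  Cells with fewer than
    ``min_trials`` trials are skipped with a warning.
    """
    probs = np.asarray(list(probs), dtype=float)
    if probs.size == 0 or np.any(np.diff(probs) <= 0):
        raise ValueError("probs must be strictly increasing")
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    if len(table) == 0:
        raise ValueError("empty trial table")
    rows = []
    skipped = 0
    for key, grp in table.groupby(_CELL_KEY, observed=True, sort=True):
        rts = grp["rt_ms"].to_numpy(dtype=float)
        rts = rts[~np.isnan(rts)]
        if rts.size < min_trials:
            skipped += 1
            continue
        q = hf_quantile8(rts, probs)
        for p, v in zip(probs, q):
            rows.append((*key, float(p), float(v)))
    if skipped:
        warnings.warn(
            f"skipped {skipped} cell(s) with fewer than {min_trials} retained trials"
        )
    if not rows:
        raise ValueError("no cell met the minimum-trial threshold")
    return pd.DataFrame(rows, columns=[*_CELL_KEY, "prob", "q_rt"])


def build_delta_dataset(cdf: pd.DataFrame) -> pd.DataFrame:
    """Delta dataset: incongruent minus congruent quantile per key.

    For every study x participant x target x prob present in both
    congruency conditions, delta = q_inc - q_cong (a negative value means
    the incongruent condition was *faster*: a reversed congruency effect)
    and mean_rt = (q_inc + q_cong) / 2, the standard delta-plot abscissa.
    Keys missing one congruency are dropped with a warning.
    """
    wide = cdf.pivot_table(
        index=["study_id", "participant_id", "target_type", "prob"],
        columns="congruency",
        values="q_rt",
        observed=True,
    )
    missing = wide.isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"dropped {int(missing.sum())} key(s) lacking one congruency condition"
        )
        wide = wide[~missing]
    out = wide.reset_index()
    out["delta"] = out["incongruent"] - out["congruent"]
    out["mean_rt"] = (out["incongruent"] + out["congruent"]) / 2.0
    return out[
        ["study_id", "participant_id", "target_type", "prob", "delta", "mean_rt"]
    ]


def vincentize(
    cells: pd.DataFrame,
    by: Sequence[str] = ("target_type",),
    value: str | None = None,
) -> pd.DataFrame:
    """Group-average participant-level quantiles (or deltas) per prob.

    ``cells`` is a CDF or delta dataset; ``by`` names the grouping roles
    (besides ``prob``).  ``value`` defaults to 'q_rt' if present, else
    'delta'.  Returns mean, SD and participant count per group x prob.
    """
    if value is None:
        value = "q_rt" if "q_rt" in cells.columns else "delta"
    keys = [*by, "prob"]
    g = cells.groupby(keys, observed=True)[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": value, "std": f"{value}_sd", "count": "n"})
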