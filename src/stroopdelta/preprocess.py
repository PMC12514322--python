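"""Trial-level exclusion, trimming and pruning rules.

The fixed pipeline order is: participant exclusion (high non-response
rate) -> keep responded trials -> RT window trim -> keep correct trials.
The final retained set is order-invariant for these filters; the fixed
order exists so removal proportions are attributed to rules reproducibly.
Only row subsets change; RT values are never modified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CONGRUENCIES, TARGET_TYPES, TRIAL_COLUMNS

__all__ = [
    "SchemaError",
    "read_trials",
    "exclude_nonresponders",
    "trim_rts",
    "filter_correct",
    "removal_report",
    "preprocess",
    "RemovalReport",
    "RT_LOW_MS",
    "RT_HIGH_MS",
    "NONRESPONSE_THRESHOLD",
]

log = logging.getLogger(__name__)

RT_LOW_MS = 200.0
RT_HIGH_MS = 1300.0
NONRESPONSE_THRESHOLD = 0.50

_REQUIRED = ["study_id", "participant_id", "target_type", "congruency", "rt_ms"]
_BOOL_TRUE = {"true", "1", "yes", "t", "correct"}
_BOOL_FALSE = {"false", "0", "no", "f", "incorrect"}


class SchemaError(ValueError):
    """A required column is missing or a category label is unknown."""


def _to_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    vals = series.astype(str).str.strip().str.lower()
    out = pd.Series(index=series.index, dtype=bool)
    ok_true = vals.isin(_BOOL_TRUE)
    ok_false = vals.isin(_BOOL_FALSE)
    bad = ~(ok_true | ok_false)
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(f"column {name!r}: unparseable boolean at row {i}: {series.iloc[i]!r}")
    out[ok_true] = True
    out[ok_false] = False
    return out


def read_trials(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trial-level CSV/TSV into the canonical trial table.

    ``column_map`` maps canonical roles (study_id, participant_id,
    target_type, congruency, rt_ms, accuracy, responded) to the file's
    column names; identity by default.  Category labels are normalized
    case-insensitively ('gaze'/'eye' map to 'eyes', 'arrow' to 'arrows').
    A missing ``responded`` column is inferred from missing RTs.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    for col in _REQUIRED:
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    df = pd.DataFrame()
    df["study_id"] = raw["study_id"].astype(str)
    df["participant_id"] = raw["participant_id"].astype(str)

    aliases = {"arrow": "arrows", "gaze": "eyes", "eye": "eyes", "faces": "face"}
    tt = raw["target_type"].astype(str).str.strip().str.lower().replace(aliases)
    bad = ~tt.isin(TARGET_TYPES)
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(f"unknown target_type {raw['target_type'].iloc[i]!r} at row {i}")
    df["target_type"] = tt

    cong = raw["congruency"].astype(str).str.strip().str.lower()
    cong = cong.replace({"cong": "congruent", "incong": "incongruent", "inc": "incongruent"})
    bad = ~cong.isin(CONGRUENCIES)
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(f"unknown congruency {raw['congruency'].iloc[i]!r} at row {i}")
    df["congruency"] = cong

    df["rt_ms"] = pd.to_numeric(raw["rt_ms"], errors="coerce")
    if "responded" in raw.columns:
        df["responded"] = _to_bool(raw["responded"], "responded")
    else:
        df["responded"] = df["rt_ms"].notna()
    if "accuracy" in raw.columns:
        df["accuracy"] = _to_bool(raw["accuracy"], "accuracy")
    else:
        df["accuracy"] = True
    df.loc[~df["responded"], "rt_ms"] = np.nan
    neg = df["responded"] & (df["rt_ms"] <= 0)
    if neg.any():
        i = int(np.nonzero(neg.to_numpy())[0][0])
        raise SchemaError(f"non-positive RT on a responded trial at row {i}")
    return df[TRIAL_COLUMNS]


def exclude_nonresponders(
    table: pd.DataFrame, threshold: float = NONRESPONSE_THRESHOLD
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop participants whose non-response proportion is >= ``threshold``.

    Returns the filtered table and the list of excluded
    (study_id, participant_id) pairs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    nr = 1.0 - table.groupby(["study_id", "participant_id"], observed=True)[
        "responded"
    ].mean()
    excluded = [tuple(k) for k in nr.index[nr >= threshold]]
    if not excluded:
        return table, []
    key = pd.MultiIndex.from_frame(table[["study_id", "participant_id"]])
    keep = ~key.isin(excluded)
    return table[keep].reset_index(drop=True), excluded


def trim_rts(
    table: pd.DataFrame,
    low: float = RT_LOW_MS,
    high: float = RT_HIGH_MS,
    mode: str = "trimmed",
) -> pd.DataFrame:
    """Apply the RT analysis window.

    mode='trimmed' keeps responded trials with low <= rt <= high (trials
    strictly faster than ``low`` or slower than ``high`` are removed, so
    boundary values are retained); mode='nontrimmed' keeps every responded
    trial regardless of RT — the robustness variant.
    """
    if low >= high:
        raise ValueError("low must be < high")
    if mode not in ("trimmed", "nontrimmed"):
        raise ValueError(f"unknown trim mode {mode!r}")
    resp = table["responded"].astype(bool)
    if mode == "nontrimmed":
        keep = resp
    else:
        keep = resp & table["rt_ms"].ge(low) & table["rt_ms"].le(high)
    return table[keep].reset_index(drop=True)


def filter_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Keep correct responses only."""
    out = table[table["accuracy"].astype(bool)].reset_index(drop=True)
    if len(out) == 0 and len(table) > 0:
        warnings.warn("no correct trials remain after accuracy filtering")
    return out


@dataclass
class RemovalReport:
    """Counts and proportions of trials removed by each pruning rule."""

    stages: pd.DataFrame  # columns: stage, removed, retained, proportion
    by_cell: pd.DataFrame = field(default_factory=pd.DataFrame)
    total_input: int = 0

    @property
    def total_removed(self) -> int:
        return int(self.stages["removed"].sum())

    def to_tsv(self, path) -> None:
        self.stages.to_csv(path, sep="\t", index=False)


def removal_report(
    before: pd.DataFrame, after_stages: dict[str, pd.DataFrame]
) -> RemovalReport:
    """Reconcile successive pipeline stages into a removal report.

    ``after_stages`` maps stage names to the table remaining after each
    rule, in application order; each must be a subset of its predecessor.
    Conservation (removed + retained == input) is enforced.
    """
    n_prev = len(before)
    total = n_prev
    recs = []
    cell_frames = []
    prev = before
    for stage, tab in after_stages.items():
        if len(tab) > n_prev:
            raise ValueError(f"stage {stage!r} has more rows than its predecessor")
        removed = n_prev - len(tab)
        recs.append(
            {
                "stage": stage,
                "removed": removed,
                "retained": len(tab),
                "proportion": removed / total if total else 0.0,
            }
        )
        # per study x target x congruency attribution for this stage
        grp = ["study_id", "target_type", "congruency"]
        b = prev.groupby(grp, observed=True).size().rename("n_before")
        a = tab.groupby(grp, observed=True).size().rename("n_after")
        cell = pd.concat([b, a], axis=1).fillna(0).astype(int).reset_index()
        cell["stage"] = stage
        cell["removed"] = cell["n_before"] - cell["n_after"]
        cell["proportion"] = np.where(
            cell["n_before"] > 0, cell["removed"] / cell["n_before"], 0.0
        )
        cell_frames.append(cell)
        prev = tab
        n_prev = len(tab)
    stages = pd.DataFrame(recs)
    report = RemovalReport(
        stages=stages,
        by_cell=pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame(),
        total_input=total,
    )
    assert report.total_removed + len(prev) == total
    return report


def preprocess(
    table: pd.DataFrame,
    *,
    low: float = RT_LOW_MS,
    high: float = RT_HIGH_MS,
    mode: str = "trimmed",
    nonresponse_threshold: float = NONRESPONSE_THRESHOLD,
) -> tuple[pd.DataFrame, RemovalReport, list[tuple[str, str]]]:
    """Run the full fixed-order pruning pipeline.

    Returns (retained table, removal report, excluded participants).
    """
    t1, excluded = exclude_nonresponders(table, nonresponse_threshold)
    t2 = t1[t1["responded"].astype(bool)].reset_index(drop=True)
    t3 = trim_rts(t2, low, high, mode)
    t4 = filter_correct(t3)
    report = removal_report(
        table,
        {
            "excluded_participant": t1,
            "nonresponse": t2,
            "rt_window": t3,
            "incorrect": t4,
        },
    )
    if excluded:
        log.info("excluded %d participant(s) for non-response: %s", len(excluded), excluded)
    return t4, report, excluded
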