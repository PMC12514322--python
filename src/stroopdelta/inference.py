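"""Mixed-model fitting, backward elimination, ANOVA, estimated marginal
means and the contrast / effect-size layer.

The two factorial models operate on the quantile datasets:

    RT model:    q_rt  ~ target * congruency + target * qq + congruency * qq
                 + (1 | study:participant) + (1 | study:target)
                 + (1 | study:target:congruency:qq)

    delta model: delta ~ target * qq
                 + (1 | study:participant) + (1 | study:target)
                 + (1 | study:target:qq)

where ``qq`` is the quantile probability treated as an unordered
five-level factor.  Denominator degrees of freedom use the Satterthwaite
approximation (recorded in every output); estimated marginal means are
taken over the equally weighted reference grid; pairwise contrasts use
Tukey HSD (studentized-range) adjustment and one-sample contrasts
against zero use Bonferroni.  Standardized effect sizes follow the
Westfall convention: the contrast divided by the square root of the sum
of all variance components including the residual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import Covariate, DesignInfo, Factor, build_design
from .mixedlm import LMMResult, RandomGrouping, VarCompLMM

__all__ = [
    "ModelSpec",
    "ModelFit",
    "rt_model_spec",
    "delta_model_spec",
    "fit_lmm",
    "anova_table",
    "partial_eta_sq",
    "stepwise_reduce",
    "emm",
    "EMMResult",
    "pairwise_tukey",
    "contrasts_vs_zero",
    "cohens_d_westfall",
]

_CANONICAL_LEVELS = {
    "target_type": ("face", "eyes", "arrows"),
    "congruency": ("congruent", "incongruent"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Response role, fixed terms and random-intercept groupings.

    ``fixed`` lists terms as tuples of variable names (mains before the
    interactions that contain them); ``random`` lists groupings as tuples
    of dataset columns whose combination keys the intercepts;
    ``covariates`` names numeric variables (everything else is a factor).
    """

    response: str
    fixed: tuple[tuple[str, ...], ...]
    random: tuple[tuple[str, ...], ...]
    covariates: tuple[str, ...] = ()

    def without_term(self, term: tuple[str, ...]) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))


def rt_model_spec() -> ModelSpec:
    """The factorial RT model on the CDF dataset."""
    return ModelSpec(
        response="q_rt",
        fixed=(
            ("target_type",),
            ("congruency",),
            ("prob",),
            ("target_type", "congruency"),
            ("target_type", "prob"),
            ("congruency", "prob"),
        ),
        random=(
            ("study_id", "participant_id"),
            ("study_id", "target_type"),
            ("study_id", "target_type", "congruency", "prob"),
        ),
    )


def delta_model_spec() -> ModelSpec:
    """The factorial delta model on the delta dataset."""
    return ModelSpec(
        response="delta",
        fixed=(("target_type",), ("prob",), ("target_type", "prob")),
        random=(
            ("study_id", "participant_id"),
            ("study_id", "target_type"),
            ("study_id", "target_type", "prob"),
        ),
    )


@dataclass
class ModelFit:
    """A fitted model together with its design metadata."""

    spec: ModelSpec
    design: DesignInfo
    result: LMMResult
    n_obs: int

    @property
    def beta(self) -> np.ndarray:
        return self.result.beta

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.result.cov_beta))
        return pd.DataFrame(
            {"term": self.design.column_names, "estimate": self.result.beta, "se": se}
        )

    def varcomp_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.result.varcomp_table())


def _level_sort_key(v: str):
    try:
        return (0, float(v), "")
    except ValueError:
        return (1, 0.0, v)


def _factor_levels(series: pd.Series, name: str) -> tuple[str, ...]:
    present = [str(v) for v in pd.unique(series.astype(str))]
    canon = _CANONICAL_LEVELS.get(name)
    if canon is not None:
        levels = tuple(lv for lv in canon if lv in present)
        extra = sorted(set(present) - set(levels))
        return levels + tuple(extra)
    return tuple(sorted(present, key=_level_sort_key))


def fit_lmm(dataset: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit ``spec`` on ``dataset`` by profiled REML.

    Factors with a single observed level contribute no fixed columns and
    any fixed term containing them is dropped (the random structure is
    keyed on the raw columns and is unaffected).
    """
    data = dataset.copy()
    fixed_vars = sorted({v for t in spec.fixed for v in t})
    variables: dict[str, Factor | Covariate] = {}
    for v in fixed_vars:
        if v in spec.covariates:
            variables[v] = Covariate(v)
        else:
            data[v] = data[v].astype(str)
            variables[v] = Factor(v, _factor_levels(data[v], v))
    degenerate = {
        v for v, var in variables.items() if isinstance(var, Factor) and var.ncols == 0
    }
    terms = [t for t in spec.fixed if not (set(t) & degenerate)]
    X, design = build_design(data, variables, terms)
    y = data[spec.response].to_numpy(dtype=float)
    groupings = []
    for cols in spec.random:
        key = pd.MultiIndex.from_frame(data[list(cols)].astype(str))
        codes, _ = pd.factorize(key, sort=True)
        groupings.append(RandomGrouping(name=":".join(cols), codes=codes))
    result = VarCompLMM(y, X, groupings).fit()
    return ModelFit(spec=spec, design=design, result=result, n_obs=len(data))


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 <= 0:
        raise ValueError("require F >= 0, df1 >= 1, df2 > 0")
    return float(F * df1 / (F * df1 + df2))


def anova_table(fit: ModelFit) -> pd.DataFrame:
    """Per-term F tests (Type-III under sum coding) with Satterthwaite df
    and partial eta squared."""
    rows = []
    for term in fit.design.terms:
        sl = fit.design.term_slices[term]
        L = np.zeros((sl.stop - sl.start, fit.design.ncols))
        L[:, sl] = np.eye(sl.stop - sl.start)
        res = fit.result.ftest(L)
        df2 = res["df2"] if np.isfinite(res["df2"]) else fit.n_obs - fit.design.ncols
        rows.append(
            {
                "term": ":".join(term),
                "F": res["F"],
                "df1": res["df1"],
                "df2": res["df2"],
                "p": res["p"],
                "eta_sq_partial": partial_eta_sq(res["F"], res["df1"], df2)
                if res["F"] > 0
                else 0.0,
                "df_method": fit.result.df_method,
            }
        )
    return pd.DataFrame(rows)


def stepwise_reduce(
    spec: ModelSpec, dataset: pd.DataFrame, alpha: float = 0.05
) -> tuple[ModelSpec, list[dict]]:
    """Backward elimination of non-significant fixed terms.

    At each step the least significant *removable* fixed term (one not
    contained in any retained interaction) with p >= alpha is dropped and
    the model refitted; the random structure is never touched.  Returns
    the reduced spec and an elimination log.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    log: list[dict] = []
    current = spec
    while True:
        fit = fit_lmm(dataset, current)
        table = anova_table(fit)
        pvals = {
            tuple(t.split(":")): p for t, p in zip(table["term"], table["p"])
        }
        removable = []
        for term in current.fixed:
            contained = any(
                set(term) < set(other) for other in current.fixed if other != term
            )
            if not contained and term in pvals and pvals[term] >= alpha:
                removable.append((pvals[term], term))
        if not removable:
            return current, log
        p, term = max(removable)
        log.append({"removed": ":".join(term), "p": float(p)})
        current = current.without_term(term)


@dataclass
class EMMResult:
    """Estimated marginal means over an equally weighted reference grid."""

    table: pd.DataFrame  # level columns + estimate, se, df, ci_low, ci_high
    factors: tuple[str, ...]
    contrast_rows: np.ndarray  # (n_means, p) design rows defining each EMM
    fit: ModelFit


def emm(
    fit: ModelFit, factors, level: float = 0.95, covariates: dict | None = None
) -> EMMResult:
    """EMMs for ``factors``, averaging over the other factors' levels with
    equal weights (covariates held at 0, i.e. their centered mean)."""
    factors = tuple(factors)
    model_factors = {
        name: var
        for name, var in fit.design.variables.items()
        if isinstance(var, Factor) and var.ncols > 0
    }
    for f in factors:
        if f not in model_factors:
            raise ValueError(f"{f!r} is not a factor in this model")
    others = [f for f in model_factors if f not in factors]
    recs = []
    rows = []
    combos = list(itertools.product(*[model_factors[f].levels for f in factors]))
    for combo in combos:
        base = dict(zip(factors, combo))
        grid = list(itertools.product(*[model_factors[f].levels for f in others]))
        r = np.zeros(fit.design.ncols)
        for other_combo in grid or [()]:
            levels = dict(base)
            levels.update(dict(zip(others, other_combo)))
            r += fit.design.row(levels, covariates)
        r /= max(len(grid), 1)
        test = fit.result.contrast_test(r)
        tcrit = (
            stats.t.ppf(0.5 + level / 2, test["df"])
            if np.isfinite(test["df"])
            else stats.norm.ppf(0.5 + level / 2)
        )
        recs.append(
            {
                **dict(zip(factors, combo)),
                "estimate": test["estimate"],
                "se": test["se"],
                "df": test["df"],
                "ci_low": test["estimate"] - tcrit * test["se"],
                "ci_high": test["estimate"] + tcrit * test["se"],
            }
        )
        rows.append(r)
    return EMMResult(
        table=pd.DataFrame(recs),
        factors=factors,
        contrast_rows=np.asarray(rows),
        fit=fit,
    )


def cohens_d_westfall(estimate: float, variance_components) -> float:
    """Standardized contrast: estimate / sqrt(sum of all variance
    components including the residual)."""
    vc = np.asarray(list(variance_components), dtype=float)
    if np.any(vc < 0):
        raise ValueError("variance components must be >= 0")
    total = vc.sum()
    if total <= 0:
        raise ValueError("all variance components are zero")
    return float(estimate / np.sqrt(total))


def _emm_contrast(emms: EMMResult, c_rows: np.ndarray) -> dict:
    return emms.fit.result.contrast_test(c_rows)


def pairwise_tukey(
    emms: EMMResult, factor: str, by: str | None = None, level: float = 0.95
) -> pd.DataFrame:
    """All pairwise EMM differences for ``factor`` (optionally within each
    level of ``by``) with Tukey HSD (studentized-range) adjusted p values
    and Westfall standardized effect sizes."""
    tab = emms.table
    if factor not in emms.factors:
        raise ValueError(f"{factor!r} not among the EMM factors")
    groups = tab.groupby(by, observed=True, sort=False) if by else [(None, tab)]
    total_var = emms.fit.result.total_variance
    recs = []
    for by_level, sub in groups:
        idx = sub.index.to_numpy()
        k = len(idx)
        for i, j in itertools.combinations(range(k), 2):
            a, b = idx[i], idx[j]
            c = emms.contrast_rows[a] - emms.contrast_rows[b]
            t_res = _emm_contrast(emms, c)
            df = t_res["df"]
            df_use = df if np.isfinite(df) else 1e6
            p_raw = t_res["p"]
            p_adj = float(
                np.clip(
                    stats.studentized_range.sf(abs(t_res["t"]) * np.sqrt(2.0), k, df_use),
                    0.0,
                    1.0,
                )
            ) if k > 1 else p_raw
            p_adj = max(p_adj, p_raw) if k == 2 else p_adj
            qcrit = stats.studentized_range.ppf(level, k, df_use) / np.sqrt(2.0)
            rec = {
                "contrast": f"{tab.loc[a, factor]} - {tab.loc[b, factor]}",
                "estimate": t_res["estimate"],
                "se": t_res["se"],
                "df": df,
                "t": t_res["t"],
                "p_raw": p_raw,
                "p_adj": p_adj,
                "adjustment": "tukey",
                "d": cohens_d_westfall(t_res["estimate"], [total_var]),
                "ci_low": t_res["estimate"] - qcrit * t_res["se"],
                "ci_high": t_res["estimate"] + qcrit * t_res["se"],
            }
            if by:
                rec[by] = by_level
            recs.append(rec)
    return pd.DataFrame(recs)


def contrasts_vs_zero(
    emms: EMMResult, adjust: str = "bonferroni", level: float = 0.95
) -> pd.DataFrame:
    """One-sample t tests of each EMM against zero; Bonferroni-adjusted p
    values (and CIs) across the whole family."""
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    m = len(emms.table)
    total_var = emms.fit.result.total_variance
    recs = []
    for i in range(m):
        c = emms.contrast_rows[i]
        t_res = _emm_contrast(emms, c)
        p_raw = t_res["p"]
        p_adj = min(1.0, m * p_raw) if adjust == "bonferroni" else p_raw
        lvl = 1.0 - (1.0 - level) / m if adjust == "bonferroni" else level
        df = t_res["df"]
        tcrit = (
            stats.t.ppf(0.5 + lvl / 2, df) if np.isfinite(df) else stats.norm.ppf(0.5 + lvl / 2)
        )
        rec = {
            **{f: emms.table.loc[i, f] for f in emms.factors},
            "estimate": t_res["estimate"],
            "se": t_res["se"],
            "df": df,
            "t": t_res["t"],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "adjustment": adjust,
            "d": cohens_d_westfall(t_res["estimate"], [total_var]),
            "ci_low": t_res["estimate"] - tcrit * t_res["se"],
            "ci_high": t_res["estimate"] + tcrit * t_res["se"],
        }
        recs.append(rec)
    return pd.DataFrame(recs)
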