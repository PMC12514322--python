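"""Polynomial trend analysis of the delta plot.

The trend model regresses the participant-level delta values on an
orthogonal quadratic polynomial of the delta-plot abscissa (the mean of
the two parent quantiles, centered within target type), crossed with
target type:

    delta ~ target * (P1(meanRT) + P2(meanRT))
            + (1 | study:participant) + (1 | study:target)
            + (1 | study:target:qq)

P1/P2 are orthonormal polynomial columns (Gram-Schmidt on the centered
covariate, as in R's ``poly``), which decorrelates the linear and
quadratic terms; reported coefficients are back-transformed to the raw
scale — ms of delta per ms of meanRT for the linear term, per ms^2 for
the quadratic — so a linear coefficient of -0.2 means the congruency
effect drops by 2 ms per 10 ms of response slowing.  Per-target
coefficients and their pairwise differences (Bonferroni-adjusted within
each degree) quantify how delta-plot shape differs between targets.
The trend model is never subjected to stepwise reduction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import Factor
from .inference import ModelFit, ModelSpec, fit_lmm

__all__ = [
    "orthopoly_basis",
    "OrthoPolyBasis",
    "fit_trend_model",
    "trend_model_spec",
    "compare_trends",
    "TrendResult",
]


@dataclass(frozen=True)
class OrthoPolyBasis:
    """Orthonormal polynomial columns of a covariate plus the linear map
    back to raw monomial coefficients.

    ``raw_transform`` is the (degree x degree) matrix T with
    ``B = 1 a' + P T`` where P holds the centered monomials
    ``(x - center)^j``; raw coefficients are ``T @ theta`` for orthogonal
    coefficients ``theta``.
    """

    columns: np.ndarray  # (n, degree), orthonormal, orthogonal to constant
    center: float
    raw_transform: np.ndarray  # (degree, degree)
    const_part: np.ndarray  # (degree,)


def orthopoly_basis(x, degree: int = 2, center: float | None = None) -> OrthoPolyBasis:
    """Orthonormal polynomial basis of ``x`` up to ``degree``.

    Columns are mutually orthogonal, orthogonal to the constant, and have
    unit norm (QR factorisation of the centered Vandermonde matrix, sign
    fixed so the leading monomial coefficient is positive).  Requires at
    least ``degree + 1`` distinct values.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct covariate values, "
            f"got {np.unique(x).size}"
        )
    c = float(np.mean(x)) if center is None else float(center)
    xc = x - c
    V = np.column_stack([xc**j for j in range(degree + 1)])  # includes constant
    Q, R = np.linalg.qr(V)
    # fix signs: diagonal of R positive => leading coefficient positive
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    B = Q[:, 1:]
    # express B in terms of [1, xc, xc^2, ...]: G = lstsq(V, B)
    G, *_ = np.linalg.lstsq(V, B, rcond=None)
    return OrthoPolyBasis(
        columns=B, center=c, raw_transform=G[1:, :], const_part=G[0, :]
    )


def trend_model_spec() -> ModelSpec:
    return ModelSpec(
        response="delta",
        fixed=(
            ("target_type",),
            ("poly1",),
            ("poly2",),
            ("target_type", "poly1"),
            ("target_type", "poly2"),
        ),
        random=(
            ("study_id", "participant_id"),
            ("study_id", "target_type"),
            ("study_id", "target_type", "prob"),
        ),
        covariates=("poly1", "poly2"),
    )


@dataclass
class TrendFit:
    """Fitted trend model plus the basis needed for raw-scale reporting."""

    fit: ModelFit
    basis: OrthoPolyBasis
    data: pd.DataFrame


def fit_trend_model(delta_dataset: pd.DataFrame, degree: int = 2) -> TrendFit:
    """Fit the trend model on a delta dataset (needs a ``mean_rt`` column).

    The abscissa is centered within target type before the orthogonal
    basis is constructed, so each target's linear coefficient is its
    delta-plot slope at that target's own mean latency.
    """
    if degree != 2:
        raise NotImplementedError("the trend model is quadratic (degree=2)")
    data = delta_dataset.copy()
    data["mean_rt_c"] = data["mean_rt"] - data.groupby(
        "target_type", observed=True
    )["mean_rt"].transform("mean")
    basis = orthopoly_basis(data["mean_rt_c"].to_numpy(), degree=degree, center=0.0)
    data["poly1"] = basis.columns[:, 0]
    data["poly2"] = basis.columns[:, 1]
    fit = fit_lmm(data, trend_model_spec())
    return TrendFit(fit=fit, basis=basis, data=data)


@dataclass
class TrendResult:
    """Raw-scale per-target polynomial coefficients and their pairwise
    differences."""

    coefficients: pd.DataFrame  # target, degree, estimate, se, df, ci, p
    differences: pd.DataFrame  # pairwise contrasts per degree, Bonferroni


def _target_coef_vector(
    trend: TrendFit, target: str, degree_idx: int
) -> np.ndarray:
    """Contrast on beta giving the raw-scale coefficient of
    (x - center)^(degree_idx+1) for ``target``.

    Orthogonal coefficients per target are theta_j(target) = beta[Pj] +
    sum-coding(target) . beta[target:Pj]; raw coefficient k is
    sum_j T[k, j] * theta_j(target).
    """
    design = trend.fit.design
    T = trend.basis.raw_transform
    degree = T.shape[0]
    p = design.ncols
    c = np.zeros(p)
    tt = design.variables.get("target_type")
    has_target = isinstance(tt, Factor) and tt.ncols > 0
    for j in range(degree):
        w = T[degree_idx, j]
        if w == 0.0:
            continue
        term = (f"poly{j + 1}",)
        c[design.term_slices[term]] += w
        if has_target:
            iterm = ("target_type", f"poly{j + 1}")
            if iterm in design.term_slices:
                li = tt.levels.index(target)
                c[design.term_slices[iterm]] += w * tt.coding()[li]
    return c


def compare_trends(
    trend: TrendFit, adjust: str = "bonferroni", level: float = 0.95
) -> TrendResult:
    """Per-target raw-scale linear/quadratic coefficients with CIs, plus
    all pairwise between-target differences per degree with
    Bonferroni-adjusted p values."""
    design = trend.fit.design
    tt = design.variables.get("target_type")
    if isinstance(tt, Factor) and tt.ncols > 0:
        targets = list(tt.levels)
    else:
        targets = [str(trend.data["target_type"].iloc[0])]
    degree_names = {0: "linear", 1: "quadratic"}
    coef_recs = []
    for target in targets:
        for k in degree_names:
            c = _target_coef_vector(trend, target, k)
            res = trend.fit.result.contrast_test(c)
            tcrit = (
                stats.t.ppf(0.5 + level / 2, res["df"])
                if np.isfinite(res["df"])
                else stats.norm.ppf(0.5 + level / 2)
            )
            coef_recs.append(
                {
                    "target_type": target,
                    "degree": degree_names[k],
                    "estimate": res["estimate"],
                    "se": res["se"],
                    "df": res["df"],
                    "t": res["t"],
                    "p": res["p"],
                    "ci_low": res["estimate"] - tcrit * res["se"],
                    "ci_high": res["estimate"] + tcrit * res["se"],
                }
            )
    diff_recs = []
    pairs = list(itertools.combinations(targets, 2))
    m = len(pairs)
    for k in degree_names:
        for a, b in pairs:
            c = _target_coef_vector(trend, a, k) - _target_coef_vector(trend, b, k)
            res = trend.fit.result.contrast_test(c)
            p_adj = (
                min(1.0, m * res["p"]) if adjust == "bonferroni" and m > 0 else res["p"]
            )
            diff_recs.append(
                {
                    "degree": degree_names[k],
                    "contrast": f"{a} - {b}",
                    "estimate": res["estimate"],
                    "se": res["se"],
                    "df": res["df"],
                    "t": res["t"],
                    "p_raw": res["p"],
                    "p_adj": p_adj,
                    "adjustment": adjust,
                }
            )
    return TrendResult(
        coefficients=pd.DataFrame(coef_recs), differences=pd.DataFrame(diff_recs)
    )
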