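"""Variance-components linear mixed models by profiled REML, with
Satterthwaite denominator degrees of freedom.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),  e ~ N(0, s2 I),

with each ``Z_k`` an indicator matrix of a categorical grouping (random
intercepts only — the structure used throughout this package: nested
study / participant / cell intercepts).  Writing ``gamma_k = s2_k / s2``
and ``W = I + Z Gamma Z'``, the residual variance profiles out of the
REML criterion, which is minimised over ``log gamma`` by bounded
quasi-Newton (L-BFGS-B) from fixed starting values (all components equal
to the residual variance).  All per-iteration algebra runs through the
Woodbury identity on the q x q matrix ``M = Z'Z + Gamma^{-1}``, so the
cost scales with the number of random-effect levels, not observations.

Inference on fixed effects uses the Satterthwaite approximation: for a
contrast ``c``, ``df = 2 f^2 / (g' A g)`` with ``f = c' Cov(beta) c``,
``g`` the gradient of ``f`` with respect to the variance parameters
(finite differences) and ``A`` the asymptotic covariance of the variance
parameters from the observed REML information.  Multi-row F tests
combine per-eigencontrast df in the usual way (Fai-Cornelius, as in
lmerTest).  Components estimated at the boundary (zero variance) are
flagged as singular, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, sparse, stats

__all__ = ["ConvergenceError", "RandomGrouping", "VarCompLMM", "LMMResult"]

_SINGULAR_GAMMA = 1e-6
_LOG_GAMMA_BOUNDS = (-15.0, 10.0)


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimizer diagnostics."""


@dataclass(frozen=True)
class RandomGrouping:
    """One random-intercept grouping: a name and integer level codes."""

    name: str
    codes: np.ndarray  # (n,) int, levels 0..n_levels-1

    @property
    def n_levels(self) -> int:
        return int(self.codes.max()) + 1 if self.codes.size else 0


def _build_z(groupings: list[RandomGrouping]) -> tuple[sparse.csr_matrix, np.ndarray]:
    n = groupings[0].codes.size
    cols = []
    comp = []
    offset = 0
    for k, g in enumerate(groupings):
        q_k = g.n_levels
        cols.append(
            sparse.csr_matrix(
                (np.ones(n), (np.arange(n), g.codes + offset)),
                shape=(n, offset + q_k),
            ).tocoo()
        )
        comp.extend([k] * q_k)
        offset += q_k
    q = offset
    rows = np.concatenate([c.row for c in cols])
    ccols = np.concatenate([c.col for c in cols])
    data = np.concatenate([c.data for c in cols])
    Z = sparse.csr_matrix((data, (rows, ccols)), shape=(n, q))
    return Z, np.asarray(comp, dtype=int)


class VarCompLMM:
    """REML fitter for a variance-components mixed model."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groupings: list[RandomGrouping],
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.groupings = list(groupings)
        self.K = len(groupings)
        for g in groupings:
            if g.n_levels < 2:
                raise ValueError(
                    f"random grouping {g.name!r} needs >= 2 levels, has {g.n_levels}"
                )
        self.Z, self.col_comp = _build_z(groupings)
        # gamma-independent cross products
        self.ZtZ = (self.Z.T @ self.Z).toarray()
        self.ZtX = self.Z.T @ self.X
        self.Zty = self.Z.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    # -- core algebra ---------------------------------------------------

    def _common(self, gamma: np.ndarray) -> dict:
        """All W-based quantities for component ratios ``gamma`` (length K)."""
        gcol = gamma[self.col_comp]
        M = self.ZtZ + np.diag(1.0 / gcol)
        cM, low = linalg.cho_factor(M, lower=True, check_finite=False)
        sv_ZtX = linalg.cho_solve((cM, low), self.ZtX, check_finite=False)
        sv_Zty = linalg.cho_solve((cM, low), self.Zty, check_finite=False)
        XtWiX = self.XtX - self.ZtX.T @ sv_ZtX
        XtWiy = self.Xty - self.ZtX.T @ sv_Zty
        ytWiy = self.yty - self.Zty @ sv_Zty
        cXX, lowX = linalg.cho_factor(XtWiX, lower=True, check_finite=False)
        beta = linalg.cho_solve((cXX, lowX), XtWiy, check_finite=False)
        qform = ytWiy - XtWiy @ beta
        logdet_M = 2.0 * np.sum(np.log(np.diag(cM)))
        logdet_W = float(np.sum(np.log(gcol)) + logdet_M)
        logdet_XtWiX = 2.0 * float(np.sum(np.log(np.diag(cXX))))
        return {
            "beta": beta,
            "qform": float(qform),
            "logdet_W": logdet_W,
            "logdet_XtWiX": logdet_XtWiX,
            "XtWiX_chol": (cXX, lowX),
        }

    def _reml_profiled(self, log_gamma: np.ndarray) -> float:
        gamma = np.exp(np.clip(log_gamma, *_LOG_GAMMA_BOUNDS))
        c = self._common(gamma)
        df = self.n - self.p
        sigma2 = max(c["qform"] / df, 1e-300)
        return (
            c["logdet_W"]
            + c["logdet_XtWiX"]
            + df * (1.0 + np.log(2.0 * np.pi * sigma2))
        )

    def _reml_full(self, v: np.ndarray) -> float:
        """-2 restricted log-likelihood at variance parameters
        ``v = (s2_1..s2_K, s2_resid)`` (unprofiled; used for the observed
        information of the variance parameters)."""
        s2 = v[-1]
        gamma = np.maximum(v[:-1], 1e-12) / s2
        c = self._common(gamma)
        df = self.n - self.p
        return (
            df * np.log(2.0 * np.pi)
            + df * np.log(s2)
            + c["logdet_W"]
            + c["logdet_XtWiX"]
            + c["qform"] / s2
        )

    def _cov_beta_at(self, v: np.ndarray) -> np.ndarray:
        s2 = v[-1]
        gamma = np.maximum(v[:-1], 1e-12) / s2
        c = self._common(gamma)
        p_eye = np.eye(self.p)
        inv = linalg.cho_solve(c["XtWiX_chol"], p_eye, check_finite=False)
        return s2 * inv

    # -- fitting --------------------------------------------------------

    def fit(self) -> "LMMResult":
        x0 = np.zeros(self.K)  # start: every component equal to residual
        res = optimize.minimize(
            self._reml_profiled,
            x0,
            method="L-BFGS-B",
            bounds=[_LOG_GAMMA_BOUNDS] * self.K,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if not res.success and "ROUNDING" not in str(res.message).upper():
            # FD gradients can stall the quasi-Newton line search near the
            # gamma -> 0 boundary; polish with derivative-free Powell.
            res2 = optimize.minimize(
                self._reml_profiled,
                res.x,
                method="Powell",
                bounds=[_LOG_GAMMA_BOUNDS] * self.K,
                options={"ftol": 1e-12, "maxiter": 1000},
            )
            if not res2.success:
                raise ConvergenceError(
                    f"REML optimisation failed: {res.message} / {res2.message}"
                )
            if res2.fun <= res.fun + 1e-8:
                res = res2
        gamma = np.exp(np.clip(res.x, *_LOG_GAMMA_BOUNDS))
        c = self._common(gamma)
        sigma2 = c["qform"] / (self.n - self.p)
        cov_beta = sigma2 * linalg.cho_solve(
            c["XtWiX_chol"], np.eye(self.p), check_finite=False
        )
        vc = gamma * sigma2
        singular = gamma <= _SINGULAR_GAMMA
        return LMMResult(
            model=self,
            beta=c["beta"],
            cov_beta=cov_beta,
            sigma2=float(sigma2),
            varcomps=vc,
            varcomp_names=[g.name for g in self.groupings],
            singular=singular,
            reml_m2ll=float(res.fun),
            n_iter=int(res.nit),
            converged=bool(res.success),
            optimizer_message=str(res.message),
        )


@dataclass
class LMMResult:
    """A fitted variance-components mixed model.

    Provides Satterthwaite t tests for arbitrary fixed-effect contrasts
    and Fai-Cornelius F tests for contrast matrices.
    """

    model: VarCompLMM
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    varcomps: np.ndarray
    varcomp_names: list[str]
    singular: np.ndarray
    reml_m2ll: float
    n_iter: int
    converged: bool
    optimizer_message: str
    df_method: str = "satterthwaite"
    _vcov_vc: np.ndarray | None = field(default=None, repr=False)
    _fd_cache: dict | None = field(default=None, repr=False)

    # -- variance-parameter machinery -----------------------------------

    @property
    def vparams(self) -> np.ndarray:
        return np.concatenate([self.varcomps, [self.sigma2]])

    def _steps(self) -> np.ndarray:
        v = self.vparams
        return 1e-4 * np.maximum(v, 1e-3 * self.sigma2)

    def varcomp_cov(self) -> np.ndarray:
        """Asymptotic covariance of (s2_1..s2_K, s2_resid) from the
        observed REML information (finite-difference Hessian)."""
        if self._vcov_vc is None:
            v = self.vparams
            h = self._steps()
            m = v.size
            H = np.zeros((m, m))
            f = self.model._reml_full
            for i in range(m):
                for j in range(i, m):
                    ei = np.zeros(m)
                    ej = np.zeros(m)
                    ei[i] = h[i]
                    ej[j] = h[j]
                    H[i, j] = H[j, i] = (
                        f(v + ei + ej) - f(v + ei - ej) - f(v - ei + ej) + f(v - ei - ej)
                    ) / (4.0 * h[i] * h[j])
            # Var(v) ~ 2 * inv(Hessian of -2 logLik)
            self._vcov_vc = 2.0 * np.linalg.pinv(H, hermitian=True)
        return self._vcov_vc

    def _cov_beta_perturbed(self) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Cache Cov(beta) at +/- steps of each variance parameter."""
        if self._fd_cache is None:
            v = self.vparams
            h = self._steps()
            pairs = []
            for i in range(v.size):
                e = np.zeros(v.size)
                e[i] = h[i]
                pairs.append(
                    (self.model._cov_beta_at(v + e), self.model._cov_beta_at(v - e))
                )
            self._fd_cache = {"h": h, "pairs": pairs}
        return self._fd_cache["h"], self._fd_cache["pairs"]

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast ``c'beta``."""
        c = np.asarray(c, dtype=float)
        f0 = float(c @ self.cov_beta @ c)
        if f0 <= 0:
            return np.inf
        h, pairs = self._cov_beta_perturbed()
        g = np.array(
            [(c @ cp @ c - c @ cm @ c) / (2.0 * hi) for (cp, cm), hi in zip(pairs, h)]
        )
        A = self.varcomp_cov()
        denom = float(g @ A @ g)
        if denom <= 0 or not np.isfinite(denom):
            return np.inf
        df = 2.0 * f0 * f0 / denom
        return float(np.clip(df, 1.0, 1e8))

    # -- tests ----------------------------------------------------------

    def contrast_test(self, c: np.ndarray) -> dict:
        """t test of H0: c'beta = 0 with Satterthwaite df."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(max(c @ self.cov_beta @ c, 0.0)))
        df = self.satterthwaite_df(c)
        t = est / se if se > 0 else 0.0
        if np.isfinite(df):
            p = 2.0 * stats.t.sf(abs(t), df)
        else:
            p = 2.0 * stats.norm.sf(abs(t))
        return {"estimate": est, "se": se, "df": df, "t": t, "p": float(p)}

    def ftest(self, L: np.ndarray) -> dict:
        """F test of H0: L beta = 0 (L: q x p), Satterthwaite-combined df."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        M = L @ self.cov_beta @ L.T
        lam, U = np.linalg.eigh(M)
        tol = max(M.shape) * np.finfo(float).eps * max(lam.max(), 1.0)
        keep = lam > tol
        q = int(keep.sum())
        if q == 0:
            return {"F": 0.0, "df1": 0, "df2": np.inf, "p": 1.0}
        lam = lam[keep]
        U = U[:, keep]
        b = U.T @ (L @ self.beta)
        t2 = b * b / lam
        F = float(t2.sum() / q)
        nus = []
        for i in range(q):
            li = L.T @ U[:, i]
            nus.append(self.satterthwaite_df(li))
        nus = np.asarray(nus)
        finite = np.isfinite(nus) & (nus > 2.0)
        if finite.all():
            E = float(np.sum(nus / (nus - 2.0)))
            df2 = 2.0 * E / (E - q) if E > q else np.inf
        else:
            df2 = np.inf
        if np.isfinite(df2):
            p = float(stats.f.sf(F, q, df2))
        else:
            p = float(stats.chi2.sf(F * q, q))
        return {"F": F, "df1": q, "df2": float(df2), "p": p}

    # -- summaries ------------------------------------------------------

    def varcomp_table(self) -> list[dict]:
        rows = [
            {
                "grouping": name,
                "variance": float(v),
                "sd": float(np.sqrt(max(v, 0.0))),
                "singular": bool(s),
            }
            for name, v, s in zip(self.varcomp_names, self.varcomps, self.singular)
        ]
        rows.append(
            {
                "grouping": "residual",
                "variance": float(self.sigma2),
                "sd": float(np.sqrt(self.sigma2)),
                "singular": False,
            }
        )
        return rows

    @property
    def total_variance(self) -> float:
        """Sum of all variance components including residual (the Westfall
        standardizer denominator, squared)."""
        return float(self.varcomps.sum() + self.sigma2)
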