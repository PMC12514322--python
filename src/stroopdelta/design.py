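"""Fixed-effect design construction with sum-to-zero factor coding.

Factors are coded with deviation (sum) contrasts so that term-wise F
tests on coefficient blocks are Type-III-style tests and the intercept is
the equally weighted grand mean — the reference-grid convention used by
the estimated-marginal-means layer.  Continuous covariates (e.g.
orthogonal polynomial columns in the trend model) enter as single
columns and may interact with factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd

__all__ = ["Factor", "Covariate", "DesignInfo", "build_design"]


@dataclass(frozen=True)
class Factor:
    """A categorical variable with a fixed, ordered level vocabulary."""

    name: str
    levels: tuple[str, ...]

    @property
    def ncols(self) -> int:
        return len(self.levels) - 1

    def coding(self) -> np.ndarray:
        """(L, L-1) sum-contrast matrix: last level is -1 on every column."""
        L = len(self.levels)
        C = np.eye(L, L - 1)
        C[-1, :] = -1.0
        return C

    def codes(self, values: pd.Series) -> np.ndarray:
        idx = pd.Categorical(values, categories=list(self.levels)).codes
        if (idx < 0).any():
            bad = values[idx < 0].iloc[0]
            raise ValueError(f"factor {self.name!r}: unknown level {bad!r}")
        return np.asarray(idx)

    def column_names(self) -> list[str]:
        return [f"{self.name}[{lv}]" for lv in self.levels[:-1]]


@dataclass(frozen=True)
class Covariate:
    """A numeric design variable (one column)."""

    name: str

    @property
    def ncols(self) -> int:
        return 1

    def column_names(self) -> list[str]:
        return [self.name]


@dataclass
class DesignInfo:
    """Maps model terms to design-matrix column blocks."""

    variables: dict[str, Factor | Covariate]
    terms: list[tuple[str, ...]]
    term_slices: dict[tuple[str, ...], slice]
    column_names: list[str]

    @property
    def ncols(self) -> int:
        return len(self.column_names)

    def row(
        self,
        levels: dict[str, str] | None = None,
        covariates: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Design row for a single (prediction) point.

        ``levels`` gives one level per factor; ``covariates`` one value per
        covariate (default 0.0, i.e. the centered covariate mean).
        """
        levels = levels or {}
        covariates = covariates or {}
        row = np.zeros(self.ncols)
        row[0] = 1.0
        for term in self.terms:
            blocks = []
            for vname in term:
                var = self.variables[vname]
                if isinstance(var, Factor):
                    if vname not in levels:
                        raise KeyError(f"level for factor {vname!r} not given")
                    li = var.levels.index(levels[vname])
                    blocks.append(var.coding()[li])
                else:
                    blocks.append(np.array([covariates.get(vname, 0.0)]))
            vals = reduce(lambda a, b: np.outer(a, b).ravel(), blocks)
            row[self.term_slices[term]] = vals
        return row


def build_design(
    data: pd.DataFrame,
    variables: dict[str, Factor | Covariate],
    terms: list[tuple[str, ...]],
) -> tuple[np.ndarray, DesignInfo]:
    """Assemble the fixed-effect matrix: intercept plus one block per term.

    Interaction columns are elementwise products of their components'
    columns; the block order follows ``terms``.
    """
    n = len(data)
    var_cols: dict[str, np.ndarray] = {}
    for vname, var in variables.items():
        if isinstance(var, Factor):
            var_cols[vname] = var.coding()[var.codes(data[vname])]
        else:
            var_cols[vname] = data[vname].to_numpy(dtype=float)[:, None]

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["(Intercept)"]
    slices: dict[tuple[str, ...], slice] = {}
    start = 1
    for term in terms:
        cols = [var_cols[v] for v in term]
        block = reduce(
            lambda a, b: (a[:, :, None] * b[:, None, :]).reshape(n, -1), cols
        )
        blocks.append(block)
        nm = [variables[v].column_names() for v in term]
        tn = reduce(lambda a, b: [f"{x}:{y}" for x in a for y in b], nm)
        names.extend(tn)
        slices[term] = slice(start, start + block.shape[1])
        start += block.shape[1]
    X = np.hstack(blocks)
    info = DesignInfo(
        variables=dict(variables),
        terms=list(terms),
        term_slices=slices,
        column_names=names,
    )
    return X, info
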