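"""Design matrices with named terms for distance-based regression.

A design is an n x p matrix with an explicit term map: which columns
belong to the intercept, the group dummies, age, sex, the sex-by-group
interaction, and the optional ordinal covariates (7 income brackets,
4 parental-education levels; missing values become an explicit level).
Categorical terms are dummy-coded against the first observed level.
Aliased (rank-deficient) columns are dropped with a log message before
any statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["DesignMatrix", "build_design", "hat_matrix"]


@dataclass(frozen=True)
class DesignMatrix:
    X: np.ndarray
    columns: tuple[str, ...]
    terms: dict[str, tuple[int, ...]]  # term name -> column indices (intercept excluded)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def reduced(self, drop_term: str) -> "DesignMatrix":
        """Design with one term's columns removed (for R^2 increments)."""
        if drop_term not in self.terms:
            raise KeyError(f"term {drop_term!r} not in design {sorted(self.terms)}")
        drop = set(self.terms[drop_term])
        keep = [j for j in range(self.X.shape[1]) if j not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        terms = {
            t: tuple(remap[j] for j in idx)
            for t, idx in self.terms.items() if t != drop_term
        }
        return DesignMatrix(self.X[:, keep], tuple(self.columns[j] for j in keep), terms)

    def subset(self, rows: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(self.X[rows], self.columns, dict(self.terms))


def hat_matrix(X: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) via SVD; returns (H, rank)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > tol * max(s[0], 1.0)).sum()) if s.size else 0
    Ur = U[:, :r]
    return Ur @ Ur.T, r


def _dummies(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Dummy-code against the first observed level; NaN -> 'missing' level."""
    s = pd.Series(values).astype(object)
    s = s.where(pd.notna(s), "missing")
    levels = list(dict.fromkeys(s))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((s == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    if not cols:
        return np.empty((len(s), 0)), []
    return np.column_stack(cols), names


def build_design(
    cohort: pd.DataFrame,
    terms: tuple[str, ...] = ("group", "age", "sex"),
    interaction: bool = False,
) -> DesignMatrix:
    """Assemble the model design from a validated cohort table.

    ``terms`` may contain ``group``, ``age``, ``sex``, ``income``,
    ``education``; ``interaction=True`` adds sex-by-group product columns
    as a single ``sex_x_group`` term.
    """
    n = len(cohort)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    term_map: dict[str, list[int]] = {}
    group_block = sex_block = None

    def add(term: str, block: np.ndarray, block_names: list[str]) -> None:
        if block.shape[1] == 0:
            raise ValueError(f"term {term!r} has no estimable columns")
        start = sum(b.shape[1] for b in blocks)
        blocks.append(block)
        names.extend(block_names)
        term_map[term] = list(range(start, start + block.shape[1]))

    for term in terms:
        if term == "group":
            group_block, gnames = _dummies(cohort["group"], "group")
            add("group", group_block, gnames)
        elif term == "age":
            add("age", cohort["age_years"].to_numpy(dtype=float)[:, None], ["age"])
        elif term == "sex":
            sex_block, snames = _dummies(cohort["sex"], "sex")
            add("sex", sex_block, snames)
        elif term == "income":
            blk, bn = _dummies(cohort["income_bracket"], "income")
            add("income", blk, bn)
        elif term == "education":
            blk, bn = _dummies(cohort["parental_education"], "education")
            add("education", blk, bn)
        else:
            raise ValueError(f"unknown term {term!r}")

    if interaction:
        if group_block is None or sex_block is None:
            raise ValueError("interaction requires both group and sex terms")
        prod = np.column_stack([
            group_block[:, j] * sex_block[:, k]
            for j in range(group_block.shape[1]) for k in range(sex_block.shape[1])
        ])
        pn = [f"sexxgroup[{j}]" for j in range(prod.shape[1])]
        add("sex_x_group", prod, pn)

    X = np.column_stack(blocks)
    # aliasing repair: greedily drop columns that do not increase rank
    keep = [0]
    rank = 1
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            log.warning("dropping aliased design column %s", names[j])
    if len(keep) < X.shape[1]:
        remap = {old: new for new, old in enumerate(keep)}
        term_map = {
            t: [remap[j] for j in idx if j in remap] for t, idx in term_map.items()
        }
        term_map = {t: idx for t, idx in term_map.items() if idx}
        names = [names[j] for j in keep]
        X = X[:, keep]
    return DesignMatrix(X, tuple(names), {t: tuple(v) for t, v in term_map.items()})
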