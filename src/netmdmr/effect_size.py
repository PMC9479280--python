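"""Jack-knife permutation effect sizes for individual outcome columns.

The multivariate group difference detected by MDMR is attributed to the
individual ROI columns by systematically dissociating one outcome at a
time from the predictors: column q of Y is shuffled across participants,
a new distance matrix D_k is computed from the shuffled Y_k and regressed
on X, and the term's pseudo-R^2 is recorded.  The effect size of column q
is

    delta_q = pseudo-R^2(observed) - mean_k pseudo-R^2(shuffled q),

averaged over K independent shuffles.  delta is a *relative* attribution:
it scales with the dimensionality and covariance of Y and must not be
compared across studies.  A Monte-Carlo standard error (SD of the
shuffled pseudo-R^2 over K, divided by sqrt(K)) is reported per cell.

Both shipped metrics decompose additively over columns (Manhattan in d,
Euclidean in d^2), so each shuffle only permutes one column's pairwise
contribution — the K-shuffle loop runs in O(K n^2) per column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import DesignMatrix, hat_matrix
from .mdmr import _double_center

log = logging.getLogger(__name__)

__all__ = ["jackknife_effect_sizes", "rank_regions"]


def _term_r2(G: np.ndarray, H_full: np.ndarray, H_red: np.ndarray) -> float:
    return float(((H_full * G).sum() - (H_red * G).sum()) / np.trace(G))


def jackknife_effect_sizes(
    Y: pd.DataFrame,
    design: DesignMatrix,
    term: str,
    metric: str = "manhattan",
    K: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """delta per outcome column for one design term.

    Returns a DataFrame indexed by column with ``delta``, ``mc_se``,
    ``r2_observed``, ``r2_shuffled_mean`` and ``K``.  Deterministic given
    ``seed``; a constant column (shuffling is a no-op) gets delta = 0
    with a warning.
    """
    if K < 100:
        raise ValueError("K must be >= 100")
    if term not in design.terms:
        raise KeyError(f"term {term!r} not in design")
    arr = np.asarray(Y, dtype=float)
    n, q = arr.shape
    if design.n != n:
        raise ValueError("design rows misaligned with Y")
    rng = np.random.default_rng(seed)

    H_full, _ = hat_matrix(design.X)
    H_red, _ = hat_matrix(design.reduced(term).X)

    # per-column pairwise contributions; metric-additive decomposition
    diffs = np.abs(arr[:, None, :] - arr[None, :, :])  # (n, n, q)
    if metric == "manhattan":
        contrib = diffs            # D = sum_q contrib_q
        total = diffs.sum(axis=2)
    elif metric == "euclidean":
        contrib = diffs**2         # D^2 = sum_q contrib_q
        total = contrib.sum(axis=2)
    else:
        raise ValueError(f"unsupported metric {metric!r}")

    A_obs = -0.5 * total**2 if metric == "manhattan" else -0.5 * total
    r2_obs = _term_r2(_double_center(A_obs), H_full, H_red)

    # Both hat matrices contain the intercept, so Hd = H_full - H_red has
    # zero row and column sums: the Gower double-centering drops out of
    # the increment tr(Hd G_k) and only -sum(A_k)/n is needed for tr(G_k)
    # (A_k has zero diagonal for both metrics).
    Hd = H_full - H_red
    rows = []
    for j in range(q):
        col = arr[:, j]
        if np.ptp(col) == 0:
            log.warning("column %s is constant; shuffle is a no-op, delta = 0", Y.columns[j])
            rows.append({"delta": 0.0, "mc_se": 0.0, "r2_observed": r2_obs,
                         "r2_shuffled_mean": r2_obs, "K": K})
            continue
        rest = total - contrib[:, :, j]
        part = contrib[:, :, j]
        if metric == "manhattan":
            hd_rest = Hd * rest
            inc_const = float((Hd * rest**2).sum())
            sum_const = float((rest**2).sum() + (part**2).sum())
        else:
            inc_const = float((Hd * rest).sum())
            sum_const = float(rest.sum() + part.sum())
        hd_flat = Hd.ravel()
        if metric == "manhattan":
            hd_rest_flat = hd_rest.ravel()
            rest_flat = rest.ravel()
        r2s = np.empty(K)
        for k in range(K):
            p = np.argsort(rng.random(n))
            Pq = part[p][:, p]  # the shuffled column's pairwise contributions
            v = Pq.ravel()
            if metric == "manhattan":
                inc = -0.5 * (inc_const + 2.0 * (hd_rest_flat @ v) + (hd_flat @ (v * v)))
                tot = -0.5 * (sum_const + 2.0 * (rest_flat @ v))
            else:
                inc = -0.5 * (inc_const + hd_flat @ v)
                tot = -0.5 * sum_const
            r2s[k] = inc / (-tot / n)
        rows.append({
            "delta": r2_obs - r2s.mean(),
            "mc_se": r2s.std(ddof=1) / np.sqrt(K),
            "r2_observed": r2_obs,
            "r2_shuffled_mean": r2s.mean(),
            "K": K,
        })
    out = pd.DataFrame(rows, index=pd.Index(Y.columns, name="column"))
    out["term"] = term
    return out


def rank_regions(table: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Sort an effect-size table by delta descending, ties lexicographic.

    ``top_k=None`` returns all rows ordered; ``top_k`` larger than the
    table is an error.
    """
    if top_k is not None and top_k > len(table):
        raise ValueError(f"top_k={top_k} exceeds {len(table)} regions")
    ordered = table.copy()
    ordered["_name"] = ordered.index.astype(str)
    ordered = ordered.sort_values(["delta", "_name"], ascending=[False, True],
                                  kind="mergesort").drop(columns="_name")
    return ordered if top_k is None else ordered.head(top_k)
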