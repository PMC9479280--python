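"""Distance-based redundancy analysis (dbRDA) and exact centroid geometry.

dbRDA visualizes a distance-based group difference by eigen-decomposing
the portion of the Gower matrix explained by the constraint (here, the
IQ-trajectory group), optionally after partialling out covariates.  With
H_c the hat matrix of the covariate-residualized constraint block and
G_p the covariate-partialled Gower matrix, the constrained axes are the
eigenvectors of H_c G_p H_c; participant scores are eigenvectors scaled
by sqrt(eigenvalue).  Three groups yield at most two constrained axes.

Exact between-centroid distances are computed directly from G via the
indicator-vector identity d^2(u, v) = e_u'Ge_u + e_v'Ge_v - 2 e_u'Ge_v
(e_g the group indicator scaled by 1/n_g), which uses the full geometry
including any negative-eigenvalue part of an indefinite (e.g. Manhattan)
G; a negative squared distance is flagged, never clipped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix, hat_matrix

__all__ = ["OrdinationResult", "dbrda", "centroid_geometry"]


@dataclass(frozen=True)
class OrdinationResult:
    eigenvalues: np.ndarray          # constrained axes, descending
    var_explained: np.ndarray        # fraction of tr(G_partialled) per axis
    scores: pd.DataFrame             # participants x axes ("dbRDA1", ...)
    centroids: pd.DataFrame          # group x axes
    centroid_se: pd.DataFrame        # group x axes, SD/sqrt(n_g)
    centroid_distances: pd.DataFrame  # exact pairwise distances from G
    status: str                      # "ok" | "empty"
    centroid_cov: dict | None = None  # group -> axis covariance of the mean


def dbrda(
    G: np.ndarray,
    design: DesignMatrix,
    constraint: str = "group",
    covariates: tuple[str, ...] = ("age", "sex"),
    groups: pd.Series | np.ndarray | None = None,
    index: pd.Index | None = None,
    tol: float = 1e-9,
    covariance_ellipses: bool = False,
) -> OrdinationResult:
    """Constrained ordination of G on one design term.

    ``groups`` (pass the cohort's group labels) drives the centroid
    summaries; ``covariates=()`` disables partialling.  Centroid
    uncertainty is axis-aligned per-axis SEs by default;
    ``covariance_ellipses=True`` additionally stores each group's
    covariance of the centroid (score covariance / n_g) for covariance
    ellipses.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if constraint not in design.terms:
        raise KeyError(f"constraint term {constraint!r} not in design")
    cidx = list(design.terms[constraint])
    cov_idx = [0] + [j for t in covariates for j in design.terms[t]]
    H_cov, _ = hat_matrix(design.X[:, cov_idx])
    R_cov = np.eye(n) - H_cov
    G_p = R_cov @ G @ R_cov
    Xc = R_cov @ design.X[:, cidx]
    H_c, rank_c = hat_matrix(Xc)

    M = H_c @ G_p @ H_c
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scale = max(abs(w[0]), abs(w[-1]), 1.0)
    pos = np.flatnonzero(w > tol * scale)[:rank_c]

    labels = None if groups is None else np.asarray(groups).astype(str)
    dist = centroid_geometry(G, labels) if labels is not None else pd.DataFrame()

    if pos.size == 0:
        empty = pd.DataFrame(index=index if index is not None else range(n))
        return OrdinationResult(np.array([]), np.array([]), empty,
                                pd.DataFrame(), pd.DataFrame(), dist, status="empty")

    eig = w[pos]
    axes = [f"dbRDA{i + 1}" for i in range(len(pos))]
    scores = V[:, pos] * np.sqrt(eig)
    scores = pd.DataFrame(scores, columns=axes,
                          index=index if index is not None else pd.RangeIndex(n))
    var_explained = eig / np.trace(G_p)

    centroids = pd.DataFrame(columns=axes, dtype=float)
    cent_se = pd.DataFrame(columns=axes, dtype=float)
    cent_cov: dict | None = {} if covariance_ellipses else None
    if labels is not None:
        for g in dict.fromkeys(labels):
            sub = scores.loc[labels == g]
            if len(sub) < 2:
                raise ValueError(f"group {g!r} has n < 2; centroid SE undefined")
            centroids.loc[g] = sub.mean()
            cent_se.loc[g] = sub.std(ddof=1) / np.sqrt(len(sub))
            if cent_cov is not None:
                cent_cov[g] = np.cov(sub.to_numpy().T, ddof=1) / len(sub)
    return OrdinationResult(eig, var_explained, scores, centroids, cent_se, dist,
                            status="ok", centroid_cov=cent_cov)


def centroid_geometry(G: np.ndarray, groups: np.ndarray | pd.Series,
                      tol: float = 1e-10) -> pd.DataFrame:
    """Exact pairwise distances between group centroids, from G directly.

    Returns a tidy frame (group_u, group_v, squared_distance, distance,
    negative) for every unordered pair; ``negative`` flags a squared
    distance below -tol (possible for indefinite G), in which case
    ``distance`` is sqrt(|d^2|) and should be interpreted with the flag.
    """
    G = np.asarray(G, dtype=float)
    labels = np.asarray(groups).astype(str)
    if labels.shape[0] != G.shape[0]:
        raise ValueError("group labels misaligned with G")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    e = {}
    for g in uniq:
        v = (labels == g).astype(float)
        e[g] = v / v.sum()
    rows = []
    for i, u in enumerate(uniq):
        for v in uniq[i:]:
            d2 = float(e[u] @ G @ e[u] + e[v] @ G @ e[v] - 2 * e[u] @ G @ e[v])
            rows.append({
                "group_u": u, "group_v": v,
                "squared_distance": d2,
                "distance": float(np.sqrt(abs(d2))),
                "negative": d2 < -tol,
            })
    return pd.DataFrame(rows)
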