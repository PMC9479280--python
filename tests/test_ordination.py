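"""dbRDA ordination and exact centroid geometry."""

import numpy as np
import pandas as pd
import pytest

import netmdmr as nm
from netmdmr.design import build_design
from netmdmr.mdmr import gower_center, pairwise_distances
from netmdmr.ordination import centroid_geometry, dbrda
from tests.conftest import make_cohort


def _setup(n=30, q=4, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    coh = make_cohort(n, seed=seed + 1)
    Y = rng.normal(size=(n, q))
    Y[:, 0] += shift * (coh["group"].astype(str) == "changers").to_numpy(float)
    return coh, Y


def test_euclidean_constrained_eigenvalues_match_rda_of_fitted_values():
    coh, Y = _setup(seed=2, shift=1.0)
    G = gower_center(pairwise_distances(Y, "euclidean"))
    des = build_design(coh, terms=("group",))
    res = dbrda(G, des, covariates=(), groups=coh["group"].astype(str))
    # RDA oracle: eigenvalues of the fitted-value Gram matrix from OLS of
    # centered Y on the group design
    X = des.X
    Yc = Y - Y.mean(axis=0)
    fitted = X @ np.linalg.lstsq(X, Yc, rcond=None)[0]
    w = np.linalg.eigvalsh(fitted @ fitted.T)[::-1]
    np.testing.assert_allclose(res.eigenvalues, w[:len(res.eigenvalues)], atol=1e-8)
    assert len(res.eigenvalues) <= 2  # three groups -> rank <= 2


def test_variance_accounting_for_euclidean_metric():
    coh, Y = _setup(seed=3, shift=0.8)
    G = gower_center(pairwise_distances(Y, "euclidean"))
    des = build_design(coh, terms=("group",))
    res = dbrda(G, des, covariates=(), groups=coh["group"].astype(str))
    from netmdmr.design import hat_matrix
    H, _ = hat_matrix(des.X)
    R = np.eye(len(coh)) - H
    assert res.eigenvalues.sum() == pytest.approx((H * G).sum(), abs=1e-8)
    assert (res.eigenvalues.sum() + np.trace(R @ G @ R)
            == pytest.approx(np.trace(G), abs=1e-8))


def test_scores_centered_and_eigenvalues_descending():
    coh, Y = _setup(seed=4, shift=1.2)
    G = gower_center(pairwise_distances(Y, "manhattan"))
    res = dbrda(G, build_design(coh), groups=coh["group"].astype(str))
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)
    assert set(res.centroids.index) == {"P-high", "P-low", "changers"}
    assert (res.centroid_se.to_numpy() > 0).all()


def test_centroid_distance_euclidean_oracle_and_symmetry():
    coh, Y = _setup(n=36, seed=5, shift=1.5)
    g = coh["group"].astype(str).to_numpy()
    G = gower_center(pairwise_distances(Y, "euclidean"))
    tab = centroid_geometry(G, g)
    means = {lev: Y[g == lev].mean(axis=0) for lev in np.unique(g)}
    for _, row in tab.iterrows():
        ref = np.linalg.norm(means[row.group_u] - means[row.group_v])
        assert row.distance == pytest.approx(ref, abs=1e-8)
        assert not row.negative
    self_rows = tab[tab.group_u == tab.group_v]
    assert np.allclose(self_rows.squared_distance, 0.0, atol=1e-8)


def test_centroid_distances_invariant_to_participant_reordering():
    coh, Y = _setup(n=24, seed=6, shift=1.0)
    g = coh["group"].astype(str).to_numpy()
    G = gower_center(pairwise_distances(Y, "manhattan"))
    perm = np.random.default_rng(0).permutation(len(g))
    t1 = centroid_geometry(G, g).set_index(["group_u", "group_v"])
    t2 = centroid_geometry(G[np.ix_(perm, perm)], g[perm])
    for _, row in t2.iterrows():
        key = (row.group_u, row.group_v)
        key = key if key in t1.index else key[::-1]
        assert row.squared_distance == pytest.approx(
            t1.loc[key, "squared_distance"], abs=1e-8)


def test_partialling_covariates_changes_constrained_solution():
    coh, Y = _setup(seed=7, shift=1.0)
    Y[:, 1] += 2.0 * coh["age_years"].to_numpy()
    G = gower_center(pairwise_distances(Y, "euclidean"))
    des = build_design(coh)
    with_cov = dbrda(G, des, covariates=("age", "sex"), groups=coh["group"].astype(str))
    without = dbrda(G, des, covariates=(), groups=coh["group"].astype(str))
    assert not np.allclose(with_cov.eigenvalues, without.eigenvalues[:len(with_cov.eigenvalues)])


def test_covariance_ellipse_flag_stores_centroid_covariances():
    coh, Y = _setup(seed=11, shift=1.0)
    G = gower_center(pairwise_distances(Y, "manhattan"))
    res = dbrda(G, build_design(coh), groups=coh["group"].astype(str),
                covariance_ellipses=True)
    assert set(res.centroid_cov) == {"P-high", "P-low", "changers"}
    for g, cov in res.centroid_cov.items():
        cov = np.atleast_2d(cov)
        # diagonal of the centroid covariance matches the per-axis SE^2
        np.testing.assert_allclose(np.sqrt(np.diag(cov)),
                                   res.centroid_se.loc[g].to_numpy(), atol=1e-10)


def test_degenerate_data_yields_empty_status():
    coh = make_cohort(12, seed=8)
    Y = np.ones((12, 3))
    G = gower_center(pairwise_distances(Y, "euclidean"))  # all-zero G
    res = dbrda(G, build_design(coh, terms=("group",)), covariates=(),
                groups=coh["group"].astype(str))
    assert res.status == "empty"
    assert res.eigenvalues.size == 0


def test_small_group_rejected_for_se():
    coh = make_cohort(12, seed=9, groups=["P-high"] * 11 + ["P-low"])
    rng = np.random.default_rng(1)
    G = gower_center(pairwise_distances(rng.normal(size=(12, 3)), "euclidean"))
    with pytest.raises(ValueError, match="n < 2"):
        dbrda(G, build_design(coh, terms=("group",)), covariates=(),
              groups=coh["group"].astype(str))
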