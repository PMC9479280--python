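"""MDMR core: distances, Gower centering, pseudo-F, permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netmdmr as nm
from netmdmr.design import build_design
from netmdmr.mdmr import gower_center, pairwise_distances, validate_distance_matrix
from tests.conftest import make_cohort


# ---------------------------------------------------------------- distances

def test_manhattan_closed_form_and_zero_self_distance():
    D = pairwise_distances(np.array([[1.0, 2.0], [4.0, 6.0]]), "manhattan")
    assert D[0, 1] == pytest.approx(7.0)
    D2 = pairwise_distances(np.array([[3.0, 3.0], [3.0, 3.0]]), "manhattan")
    assert D2[0, 1] == 0.0


@pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
def test_distances_match_nested_loop_reference(metric):
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(10, 5))
    D = pairwise_distances(Y, metric)
    ref = np.zeros((10, 10))
    for i in range(10):
        for j in range(10):
            d = np.abs(Y[i] - Y[j])
            ref[i, j] = d.sum() if metric == "manhattan" else np.sqrt((d**2).sum())
    np.testing.assert_allclose(D, ref, atol=1e-12)
    validate_distance_matrix(D)


def test_unknown_metric_and_missing_values_rejected():
    with pytest.raises(ValueError, match="unknown metric"):
        pairwise_distances(np.eye(3), "pearson")
    with pytest.raises(ValueError, match="missing values"):
        pairwise_distances(np.array([[1.0, np.nan], [0.0, 1.0]]), "manhattan")


# ------------------------------------------------------------------- Gower

def test_gower_row_sums_are_zero():
    rng = np.random.default_rng(2)
    G = gower_center(pairwise_distances(rng.normal(size=(12, 4)), "manhattan"))
    np.testing.assert_allclose(G.sum(axis=1), 0.0, atol=1e-8)
    np.testing.assert_allclose(G, G.T, atol=1e-12)


def test_gower_two_point_hand_computation():
    D = np.array([[0.0, 2.0], [2.0, 0.0]])
    np.testing.assert_allclose(gower_center(D), [[1.0, -1.0], [-1.0, 1.0]])


def test_euclidean_gower_equals_centered_gram():
    rng = np.random.default_rng(3)
    Y = rng.normal(size=(15, 4))
    G = gower_center(pairwise_distances(Y, "euclidean"))
    Yc = Y - Y.mean(axis=0)
    np.testing.assert_allclose(G, Yc @ Yc.T, atol=1e-10)


# ------------------------------------------------------------------ mdmr_fit

def test_univariate_euclidean_pseudo_f_equals_anova_f():
    rng = np.random.default_rng(4)
    for _ in range(10):
        coh = make_cohort(int(rng.integers(15, 40)), seed=int(rng.integers(1e6)))
        y = rng.normal(size=(len(coh), 1))
        G = gower_center(pairwise_distances(y, "euclidean"))
        res = nm.mdmr_fit(G, build_design(coh, terms=("group",)), n_perm=0)
        g = coh["group"].astype(str).to_numpy()
        f_ref = stats.f_oneway(*[y[g == lev, 0] for lev in np.unique(g)]).statistic
        assert res.terms["group"].pseudo_f == pytest.approx(f_ref, abs=1e-8)


def test_multivariate_euclidean_trace_equals_sum_of_ols_model_ss():
    rng = np.random.default_rng(5)
    coh = make_cohort(30, seed=9)
    Y = rng.normal(size=(30, 4))
    G = gower_center(pairwise_distances(Y, "euclidean"))
    des = build_design(coh)
    from netmdmr.design import hat_matrix
    H, _ = hat_matrix(des.X)
    Yc = Y - Y.mean(axis=0)
    ss_model = sum(((H @ Yc[:, q])**2).sum() for q in range(4))
    assert (H * G).sum() == pytest.approx(ss_model, rel=1e-10)


def test_permanova_oracle_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova
    rng = np.random.default_rng(6)
    coh = make_cohort(24, seed=13)
    Y = rng.normal(size=(24, 5))
    D = pairwise_distances(Y, "manhattan")
    ref = permanova(SkDM(D), grouping=list(coh["group"].astype(str)), permutations=0)
    res = nm.mdmr_fit(gower_center(D), build_design(coh, terms=("group",)), n_perm=0)
    assert res.terms["group"].pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)


def test_intercept_only_model_has_zero_pseudo_r2():
    rng = np.random.default_rng(7)
    coh = make_cohort(12, seed=3)
    G = gower_center(pairwise_distances(rng.normal(size=(12, 3)), "manhattan"))
    des = build_design(coh, terms=("age",)).reduced("age")  # intercept only
    res = nm.mdmr_fit(G, des, terms=(), n_perm=0)
    assert res.full.pseudo_r2 == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
def test_metric_scale_invariance_of_statistics_and_p(metric):
    coh = make_cohort(30, seed=21)
    rng = np.random.default_rng(8)
    Y = rng.normal(size=(30, 4))
    des = build_design(coh)
    out = []
    for c in (1.0, 7.3):
        G = gower_center(pairwise_distances(c * Y, metric))
        out.append(nm.mdmr_fit(G, des, n_perm=199, seed=5, metric=metric))
    for term in out[0].terms:
        a, b = out[0].terms[term], out[1].terms[term]
        assert a.pseudo_r2 == pytest.approx(b.pseudo_r2, abs=1e-10)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, abs=1e-8)
        assert a.perm_p == b.perm_p


def test_permutation_p_reproducible_given_seed():
    coh = make_cohort(25, seed=2)
    rng = np.random.default_rng(9)
    G = gower_center(pairwise_distances(rng.normal(size=(25, 3)), "manhattan"))
    des = build_design(coh)
    p1 = nm.mdmr_fit(G, des, n_perm=299, seed=11).terms["group"].perm_p
    p2 = nm.mdmr_fit(G, des, n_perm=299, seed=11).terms["group"].perm_p
    assert p1 == p2
    assert 1 / 300 <= p1 <= 1.0


def test_raw_permutation_scheme_also_valid():
    coh = make_cohort(25, seed=2)
    rng = np.random.default_rng(10)
    G = gower_center(pairwise_distances(rng.normal(size=(25, 3)), "manhattan"))
    res = nm.mdmr_fit(G, build_design(coh), n_perm=199, seed=0, scheme="raw")
    assert 0 < res.terms["group"].perm_p <= 1


def test_input_contract_errors():
    coh = make_cohort(10, seed=1)
    G = gower_center(pairwise_distances(np.random.default_rng(0).normal(size=(10, 2))))
    with pytest.raises(ValueError, match="n_perm"):
        nm.mdmr_fit(G, build_design(coh), n_perm=50)
    with pytest.raises(ValueError, match="misaligned"):
        nm.mdmr_fit(G, build_design(make_cohort(9, seed=1)))


# ------------------------------------------------------- pairwise / interaction

def test_pairwise_contrasts_recompute_gower_on_subset(default_cohort, default_tscores, fpn):
    cohort, _, _ = default_cohort
    Y = default_tscores[list(fpn.columns)]
    D = pairwise_distances(Y, "manhattan")
    pairs = nm.pairwise_group_contrasts(D, cohort, n_perm=99, seed=1)
    assert set(pairs) == {("P-high", "P-low"), ("P-high", "changers"),
                          ("P-low", "changers")}
    # manual recompute for one pair must agree exactly (G rebuilt on subset)
    g = cohort["group"].astype(str).to_numpy()
    idx = np.flatnonzero((g == "P-high") | (g == "changers"))
    G_sub = gower_center(D[np.ix_(idx, idx)])
    sub = cohort.iloc[idx].reset_index(drop=True)
    ref = nm.mdmr_fit(G_sub, build_design(sub), terms=("group",), n_perm=99, seed=1)
    got = pairs[("P-high", "changers")].terms["group"]
    assert got.pseudo_f == pytest.approx(ref.terms["group"].pseudo_f, abs=1e-12)
    assert got.perm_p == ref.terms["group"].perm_p
    # subsetting the full-sample G instead would be wrong: verify it differs
    G_full = gower_center(D)
    assert not np.allclose(G_full[np.ix_(idx, idx)], G_sub)


def test_pairwise_contrast_invariant_to_group_relabeling(default_cohort, default_tscores, fpn):
    cohort, _, _ = default_cohort
    D = pairwise_distances(default_tscores[list(fpn.columns)], "manhattan")
    swapped = cohort.copy()
    swap = {"P-high": "P-low", "P-low": "P-high", "changers": "changers"}
    swapped["group"] = pd.Categorical([swap[g] for g in cohort["group"].astype(str)],
                                      categories=["P-high", "P-low", "changers"])
    a = nm.pairwise_group_contrasts(D, cohort, n_perm=99, seed=3)
    b = nm.pairwise_group_contrasts(D, swapped, n_perm=99, seed=3)
    assert (a[("P-high", "P-low")].terms["group"].pseudo_f
            == pytest.approx(b[("P-high", "P-low")].terms["group"].pseudo_f, abs=1e-10))


def test_interaction_detected_and_destroyed_by_within_group_sex_shuffle():
    """A strong planted sex-by-group effect is found; shuffling sex labels
    within groups (a negative control preserving margins) removes it."""
    from netmdmr.simulate import PlantedEffect, SimulationConfig
    cells = {(g, s): 25 for g in ("P-high", "P-low", "changers")
             for s in ("male", "female")}
    cfg = SimulationConfig(
        n_per_group_by_sex=cells,
        planted_effects=(PlantedEffect("angular_gyrus_right", "sex", {"female": 3.0}),))
    cohort, vols, _ = nm.simulate_cohort(cfg, seed=17)
    # make the sex effect group-specific: flip it off outside "changers"
    Y = nm.to_tscores(nm.to_proportions(vols, cohort))
    col = Y["angular_gyrus_right"].to_numpy().copy()
    mask = (cohort["group"].astype(str) != "changers").to_numpy() \
        & (cohort["sex"].astype(str) == "female").to_numpy()
    col[mask] -= 30.0  # cancel the shift (3 SD on the T scale)
    Y = Y.assign(angular_gyrus_right=col)
    fpn_cols = [c for c in nm.load_network_spec("FPN").columns]
    G = gower_center(pairwise_distances(Y[fpn_cols], "manhattan"))
    obs = nm.interaction_test(G, cohort, n_perm=199, seed=4)
    assert obs.terms["sex_x_group"].perm_p < 0.05

    rng = np.random.default_rng(0)
    shuffled = cohort.copy()
    sex = shuffled["sex"].astype(str).to_numpy()
    for gname in ("P-high", "P-low", "changers"):
        gi = np.flatnonzero(shuffled["group"].astype(str) == gname)
        sex[gi] = sex[rng.permutation(gi)]
    shuffled["sex"] = pd.Categorical(sex, categories=["male", "female"])
    null = nm.interaction_test(G, shuffled, n_perm=199, seed=4)
    assert null.terms["sex_x_group"].perm_p > obs.terms["sex_x_group"].perm_p
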