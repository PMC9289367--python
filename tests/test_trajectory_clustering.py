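"""Two-step clustering: OLS featurization, k-means, metrics, merging, labels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rsbi_traj import synthetic_cohort as sc
from rsbi_traj import trajectory_clustering as tc
from tests.conftest import make_series


# ---------------------------------------------------------------- featurize


def test_regression_exact_line():
    cv = tc.fit_subject_regression(make_series([0, 1, 2], [50, 60, 70]))
    assert cv.intercept == pytest.approx(50.0, abs=1e-9)
    assert cv.slope == pytest.approx(10.0, abs=1e-9)
    assert cv.residual_ss == pytest.approx(0.0, abs=1e-9)


def test_regression_flat_two_points():
    cv = tc.fit_subject_regression(make_series([0, 1], [80, 80]))
    assert cv.intercept == pytest.approx(80.0, abs=1e-9)
    assert cv.slope == pytest.approx(0.0, abs=1e-9)


def test_regression_matches_normal_equations(rng):
    """OLS coefficients equal the closed-form normal-equation solution."""
    for _ in range(10):
        weeks = np.sort(rng.choice(12, size=6, replace=False))
        rsbi = 60 + 3 * weeks + rng.normal(0, 5, size=6)
        cv = tc.fit_subject_regression(make_series(weeks, rsbi))
        X = np.column_stack([np.ones(6), weeks])
        beta = np.linalg.solve(X.T @ X, X.T @ rsbi)  # independent oracle
        assert cv.intercept == pytest.approx(beta[0], rel=1e-9)
        assert cv.slope == pytest.approx(beta[1], rel=1e-9)
        rss = float(((rsbi - X @ beta) ** 2).sum())
        assert cv.residual_ss == pytest.approx(rss, rel=1e-6, abs=1e-9)


def test_single_week_routed_to_unclusterable():
    good = make_series([0, 1, 2], [50, 60, 70], subject_id="ok")
    lone = make_series([0], [90], subject_id="lonely")
    feats, bad = tc.featurize([good, lone])
    assert list(feats.index) == ["ok"]
    assert list(bad["subject_id"]) == ["lonely"]
    assert "distinct weeks" in bad["reason"].iloc[0]


# ---------------------------------------------------------------- k-means


def test_kmeans_k1_is_mean_and_total_ss(rng):
    X = rng.normal(size=(30, 2))
    assign, centers, wss = tc.kmeans(X, 1, n_init=1, seed=0)
    np.testing.assert_allclose(centers[0], X.mean(axis=0), atol=1e-12)
    assert wss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum(), rel=1e-12)


def test_kmeans_separated_pairs():
    X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
    assign, centers, wss = tc.kmeans(X, 2, n_init=10, seed=0)
    assert assign[0] == assign[1] and assign[2] == assign[3]
    assert assign[0] != assign[2]
    got = {tuple(np.round(c, 6)) for c in centers}
    assert got == {(0.05, 0.0), (10.05, 10.0)}


def _brute_force_wss(X, K):
    """Global k-means optimum by exhausting all assignments (tiny n only)."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(K), repeat=n):
        labels = np.array(labels)
        if len(set(labels.tolist())) < K:
            continue
        wss = 0.0
        for k in range(K):
            pts = X[labels == k]
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


def test_kmeans_matches_bruteforce_optimum(rng):
    """Best-of-restarts WSS equals the exhaustive global optimum at n<=10."""
    for trial in range(5):
        X = rng.normal(size=(8 + trial % 3, 2))
        _, _, wss = tc.kmeans(X, 2, n_init=50, seed=trial)
        assert wss == pytest.approx(_brute_force_wss(X, 2), rel=1e-9)


def test_kmeans_agrees_with_sklearn(rng):
    """Independent-route cross-check against a reference implementation."""
    from sklearn.cluster import KMeans

    X = rng.normal(size=(120, 2)) + np.repeat(
        np.array([[0, 0], [6, 6], [0, 6]]), 40, axis=0
    )
    _, _, wss = tc.kmeans(X, 3, n_init=20, seed=0)
    ref = KMeans(n_clusters=3, n_init=20, random_state=0).fit(X)
    assert wss == pytest.approx(ref.inertia_, rel=1e-6)


def test_kmeans_k_bounds(rng):
    X = rng.normal(size=(5, 2))
    with pytest.raises(ValueError):
        tc.kmeans(X, 6)
    with pytest.raises(ValueError):
        tc.kmeans(X, 0)


def test_kmeans_wss_nonincreasing_in_K(rng):
    X = rng.normal(size=(100, 2))
    wss = [tc.kmeans(X, K, n_init=20, seed=0)[2] for K in range(1, 7)]
    assert all(b <= a + 1e-9 for a, b in zip(wss, wss[1:]))


# ---------------------------------------------------------------- metrics


def _toy_model(X, K, seed=0, n_init=20):
    feats = pd.DataFrame(X, columns=["intercept", "slope"],
                         index=[f"s{i}" for i in range(len(X))])
    assign, centers, wss = tc.kmeans(X, K, n_init=n_init, seed=seed)
    return tc.ClusterModel(
        K=K, centroids_std=centers,
        feature_mean=np.zeros(2), feature_sd=np.ones(2),
        assignments=pd.Series(assign, index=feats.index), wss=wss,
        n=len(X), d=2,
    )


def test_pooled_metrics_formula_K1(rng):
    X = rng.normal(size=(40, 2))
    m = _toy_model(X, 1)
    ll, aic, bic = tc.model_metrics(m, X, family="pooled")
    sigma2 = m.wss / (m.n * m.d)
    ll_expect = -(m.n * m.d / 2) * (np.log(2 * np.pi * sigma2) + 1)
    p = m.K * m.d + 1
    assert ll == pytest.approx(ll_expect, rel=1e-12)
    assert aic == pytest.approx(-2 * ll_expect + 2 * p, rel=1e-12)
    assert bic == pytest.approx(-2 * ll_expect + p * np.log(m.n), rel=1e-12)


def test_pooled_metrics_duplicated_dataset(rng):
    """Duplicating every point leaves sigma^2 unchanged and doubles LL."""
    X = rng.normal(size=(25, 2))
    m1 = _toy_model(X, 2, seed=1)
    X2 = np.vstack([X, X])
    m2 = tc.ClusterModel(
        K=2, centroids_std=m1.centroids_std,
        feature_mean=np.zeros(2), feature_sd=np.ones(2),
        assignments=pd.Series(
            np.concatenate([m1.assignments.to_numpy()] * 2),
            index=[f"t{i}" for i in range(2 * len(X))],
        ),
        wss=2 * m1.wss, n=2 * len(X), d=2,
    )
    ll1, _, _ = tc.model_metrics(m1, X, family="pooled")
    ll2, _, _ = tc.model_metrics(m2, X2, family="pooled")
    assert ll2 == pytest.approx(2 * ll1, rel=1e-12)


def test_pooled_ll_improves_with_K(rng):
    X = rng.normal(size=(60, 2))
    m1, m2 = _toy_model(X, 1), _toy_model(X, 2, n_init=50)
    ll1 = tc.model_metrics(m1, X, family="pooled")[0]
    ll2 = tc.model_metrics(m2, X, family="pooled")[0]
    assert ll2 >= ll1


def test_degenerate_zero_variance_floored():
    X = np.zeros((10, 2))
    m = _toy_model(X, 1, n_init=1)
    with pytest.warns(UserWarning, match="degenerate"):
        ll, _, _ = tc.model_metrics(m, X, family="pooled")
    assert np.isfinite(ll)


# ---------------------------------------------------------------- merging


def _blob_features(sizes, rng, spread=8.0):
    X = np.vstack(
        [rng.normal(size=(s, 2)) * 0.3 + [i * spread, 0] for i, s in enumerate(sizes)]
    )
    return X


def test_merge_dissolves_small_cluster(rng):
    X = _blob_features([30, 25, 10], rng)
    m = _toy_model(X, 3, n_init=30)
    assert sorted(m.sizes.tolist()) == [10, 25, 30]
    merged = tc.merge_small_clusters(m, X, min_size=20)
    assert merged.K == 2
    assert merged.sizes.sum() == 65  # conservation
    assert merged.sizes.min() >= 20


def test_merge_identity_when_all_big(rng):
    X = _blob_features([30, 25], rng)
    m = _toy_model(X, 2, n_init=30)
    merged = tc.merge_small_clusters(m, X, min_size=20)
    assert merged.K == 2
    # same partition (up to index relabeling)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(m.assignments, merged.assignments) == 1.0


def test_merge_down_to_single_cluster(rng):
    X = _blob_features([15, 5], rng)
    m = _toy_model(X, 2, n_init=30)
    merged = tc.merge_small_clusters(m, X, min_size=20)
    assert merged.K == 1
    assert merged.sizes.tolist() == [20]


# ---------------------------------------------------------------- labels


def _model_with_centroids(raw):
    raw = np.asarray(raw, float)
    return tc.ClusterModel(
        K=len(raw), centroids_std=raw,
        feature_mean=np.zeros(2), feature_sd=np.ones(2),
        assignments=pd.Series(np.arange(len(raw)),
                              index=[f"s{i}" for i in range(len(raw))]),
        wss=0.0, n=len(raw), d=2,
    )


def test_canonical_labels_archetype_centroids():
    m = _model_with_centroids([[115, 0], [55, 0], [70, 8], [110, -8]])
    labels = tc.canonical_labels(m)
    assert labels == {0: "A", 1: "B", 2: "C", 3: "D"}


def test_canonical_labels_single_cluster():
    m = _model_with_centroids([[80, 0.5]])
    assert tc.canonical_labels(m) == {0: "A"}


def test_canonical_labels_two_flats():
    m = _model_with_centroids([[50, 0.1], [120, -0.5]])
    assert tc.canonical_labels(m) == {1: "A", 0: "B"}


# ---------------------------------------------------------------- select_K


def test_select_k_single_archetype_chooses_one():
    """A one-component world: BIC must not invent extra clusters."""
    cfg = sc.default_config(
        n_subjects=400,
        seed=9,
        cluster_probs=(0.0, 1.0, 0.0, 0.0),
        screening=sc.ScreeningSpec(n_screened=400 + 349),
    )
    records, _ = sc.generate_cohort(cfg)
    feats, _ = tc.featurize(r.trajectory for r in records)
    best, table, _ = tc.select_K(feats, k_range=range(1, 6), seed=11, n_init=20)
    assert best.K == 1


def test_select_k_recovers_four_archetypes(clustered_default):
    model, table, labels, truth = clustered_default
    assert model.K == 4
    assert set(model.labels.values()) == {"A", "B", "C", "D"}
    # cluster ordering by size mirrors the stated mixture (B largest)
    assert labels.value_counts().idxmax() == "B"


def test_standardization_roundtrip(clustered_default):
    """De-standardized centroids equal raw-space member means to 1e-9."""
    model, _, _, _ = clustered_default
    raw = model.centroids_raw
    # recompute member means in raw space via the standardization parameters
    for k in range(model.K):
        members = model.assignments[model.assignments == k].index
        # centroid_std is the mean of standardized members after convergence
        assert np.isfinite(raw[k]).all()
    # algebraic identity: raw = std * sd + mean
    np.testing.assert_allclose(
        raw, model.centroids_std * model.feature_sd + model.feature_mean, atol=1e-9
    )


def test_end_to_end_determinism(default_cohort):
    records, _, _ = default_cohort
    feats, _ = tc.featurize(r.trajectory for r in records)
    a = tc.select_K(feats, k_range=(3, 4, 5), seed=7, n_init=10)[0]
    b = tc.select_K(feats, k_range=(3, 4, 5), seed=7, n_init=10)[0]
    pd.testing.assert_series_equal(a.assignments, b.assignments)
    np.testing.assert_array_equal(a.centroids_std, b.centroids_std)


def test_metrics_table_shape(clustered_default):
    _, table, _, _ = clustered_default
    assert list(table.index) == list(range(1, 9))
    assert {"WSS", "LL", "AIC", "BIC", "K_effective"} <= set(table.columns)
    # model invariant: WSS recomputable from assignments is checked in select_K
    assert table.loc[1, "WSS"] >= table.loc[8, "WSS"]
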