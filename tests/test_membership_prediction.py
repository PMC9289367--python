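"""GBM tuning protocol, relative influence, model comparison, explainers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingClassifier

from rsbi_traj import membership_prediction as mp


def _toy_classification(n=200, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        }
    )
    if informative:
        y = np.where(X["x1"] + 0.5 * X["x2"] > 0, "pos", "neg")
    else:
        y = rng.choice(["pos", "neg"], size=n)
    return X, pd.Series(y)


SMALL_GRID = mp.TuningGrid(n_trees=(5,), tree_depth=(3,), cv_folds=5)


# ---------------------------------------------------------------- tuning


def test_grid_of_size_one_returns_that_configuration():
    X, y = _toy_classification()
    bundle = mp.tune_and_fit(X, y, grid=SMALL_GRID, seed=0)
    assert bundle.best_params["n_trees"] == 5
    assert bundle.best_params["depth"] == 3
    assert len(bundle.cv_table) == 1


def test_selected_configuration_dominates_table(tuned_bundle):
    """The chosen configuration's mean CV accuracy tops every grid row."""
    bundle, _ = tuned_bundle
    table = bundle.cv_table
    assert len(table) == 60  # full 15 x 4 Cartesian grid
    best = table["mean_accuracy"].iloc[0]
    assert (best >= table["mean_accuracy"] - 1e-12).all()
    # deterministic tie-breaking: fewer trees, then shallower
    ties = table[table["mean_accuracy"] == best]
    assert (
        table.iloc[0]["n_trees"],
        table.iloc[0]["depth"],
    ) == (ties["n_trees"].min(), ties[ties["n_trees"] == ties["n_trees"].min()]["depth"].min())


def test_class_smaller_than_folds_is_rejected():
    X, y = _toy_classification(n=30)
    y.iloc[:3] = "rare"
    y.iloc[3:] = "common"
    with pytest.raises(ValueError, match="fewer"):
        mp.tune_and_fit(X, y, grid=mp.TuningGrid(cv_folds=10), seed=0)


def test_single_class_rejected():
    X, y = _toy_classification(n=30)
    with pytest.raises(ValueError, match="classes"):
        mp.tune_and_fit(X, pd.Series(["same"] * 30), grid=SMALL_GRID, seed=0)


def test_staged_prefix_equals_separate_fit():
    """First k stages of a 15-tree fit coincide with the k-tree fit.

    This underpins reading the whole trees axis of the grid from
    staged_predict_proba of a single fit per depth.
    """
    X, y = _toy_classification(n=150, seed=3)
    Xa, ya = X.to_numpy(), y.to_numpy()
    full = GradientBoostingClassifier(
        n_estimators=15, max_depth=3, learning_rate=0.1,
        min_samples_leaf=30, random_state=0,
    ).fit(Xa, ya)
    staged = list(full.staged_predict_proba(Xa))
    for k in (1, 7, 15):
        part = GradientBoostingClassifier(
            n_estimators=k, max_depth=3, learning_rate=0.1,
            min_samples_leaf=30, random_state=0,
        ).fit(Xa, ya)
        np.testing.assert_allclose(staged[k - 1], part.predict_proba(Xa), atol=1e-12)


def test_permuted_labels_give_chance_accuracy():
    """Null-model oracle: with labels shuffled, CV accuracy ~ majority rate."""
    rng = np.random.default_rng(7)
    X, y = _toy_classification(n=400, seed=7)
    y_perm = pd.Series(rng.permutation(y.to_numpy()))
    bundle = mp.tune_and_fit(X, y_perm, grid=SMALL_GRID, seed=1)
    majority = y_perm.value_counts(normalize=True).max()
    se = np.sqrt(majority * (1 - majority) / len(y_perm))
    acc = bundle.cv_table["mean_accuracy"].iloc[0]
    assert abs(acc - majority) < 3 * se + 0.02


def test_predicted_probabilities_sum_to_one(tuned_bundle):
    bundle, X = tuned_bundle
    proba = bundle.predict_proba(X.iloc[:50])
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


# ---------------------------------------------------------------- influence


def test_relative_influence_sums_to_100(tuned_bundle):
    bundle, _ = tuned_bundle
    imp = mp.relative_influence(bundle)
    assert imp["influence"].sum() == pytest.approx(100.0, abs=1e-6)
    assert imp["influence"].is_monotonic_decreasing


def test_constant_feature_has_zero_influence():
    X, y = _toy_classification(n=200, seed=2)
    X = X.assign(never_used=1.0)
    bundle = mp.tune_and_fit(X, y, grid=SMALL_GRID, seed=0)
    imp = mp.relative_influence(bundle).set_index("feature")
    assert imp.loc["never_used", "influence"] == 0.0


def test_strong_effect_analogs_rank_high(tuned_bundle):
    """Covariates with the largest configured cluster effects lead the ranking."""
    bundle, _ = tuned_bundle
    top8 = set(mp.relative_influence(bundle)["feature"].head(8))
    for name in ("tsh", "cortisol_am", "magnesium"):
        assert name in top8


# ---------------------------------------------------------------- comparison


def test_compare_models_separable_problem_is_perfect():
    rng = np.random.default_rng(0)
    n = 120
    X = pd.DataFrame({"x": np.r_[rng.normal(-8, 0.5, n // 2), rng.normal(8, 0.5, n // 2)],
                      "z": rng.normal(size=n)})
    y = pd.Series(["lo"] * (n // 2) + ["hi"] * (n // 2))
    res = mp.compare_models(X, y, n_repeats=2, n_folds=3, seed=0)
    assert set(res["model"]) == {"GBM", "RF", "LASSO"}
    assert (res["accuracy"] == 1.0).all()
    assert (res["kappa"] == 1.0).all()


def test_compare_models_null_kappa_near_zero():
    X, y = _toy_classification(n=180, seed=11, informative=False)
    res = mp.compare_models(X, y, n_repeats=2, n_folds=3, seed=1)
    for _, grp in res.groupby("model"):
        assert abs(grp["kappa"].mean()) < 0.2  # ~3 SE of chance agreement


def test_compare_models_deterministic_given_seed():
    X, y = _toy_classification(n=90, seed=4)
    r1 = mp.compare_models(X, y, n_repeats=1, n_folds=3, seed=9)
    r2 = mp.compare_models(X, y, n_repeats=1, n_folds=3, seed=9)
    pd.testing.assert_frame_equal(r1, r2)
    summary = mp.compare_summary(r1)
    assert {"median", "min", "max"} <= set(summary.columns)


# ---------------------------------------------------------------- explainers


class _AdditiveProbaModel:
    """Stub with predict_proba additive in the features (two classes)."""

    def __init__(self, weights, bias=0.4):
        self.w = np.asarray(weights, float)
        self.b = bias

    def predict_proba(self, X):
        p = np.clip(self.b + np.asarray(X, float) @ self.w, 0.001, 0.999)
        return np.column_stack([1 - p, p])


def _stub_bundle(n=80, d=3, seed=0, weights=(0.05, -0.03, 0.0)):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, d)), columns=[f"f{i}" for i in range(d)])
    X["f2"] = 1.5  # constant across training data
    return mp.PredictorBundle(
        model=_AdditiveProbaModel(weights),
        best_params={},
        cv_table=pd.DataFrame(),
        classes=["neg", "pos"],
        feature_names=list(X.columns),
        X_train=X,
    )


def test_breakdown_conservation_real_model(tuned_bundle):
    """baseline + sum(contributions) reproduces the predicted probability."""
    bundle, X = tuned_bundle
    for sid in X.index[:3]:
        e = mp.breakdown_explain(bundle, X.loc[sid], n_orderings=5, seed=0)
        total = e.baseline + e.contributions["contribution"].sum()
        assert total == pytest.approx(e.prediction, abs=1e-6)


def test_breakdown_additive_model_matches_partial_effects():
    """On an additive model, contributions equal single-feature effects."""
    bundle = _stub_bundle()
    x = pd.Series({"f0": 2.0, "f1": -1.0, "f2": 1.5})
    e = mp.breakdown_explain(bundle, x, explain_class="pos", n_orderings=5, seed=1)
    bg = bundle.X_train.to_numpy()
    base = bundle.model.predict_proba(bg)[:, 1].mean()
    contrib = e.contributions.set_index("feature")["contribution"]
    for j, name in enumerate(bundle.feature_names):
        Z = bg.copy()
        Z[:, j] = x[name]
        partial = bundle.model.predict_proba(Z)[:, 1].mean() - base
        assert contrib[name] == pytest.approx(partial, abs=1e-9)
    assert e.interactions.empty  # additive model has no interactions


def test_breakdown_constant_feature_zero_contribution():
    bundle = _stub_bundle()
    x = pd.Series({"f0": 0.3, "f1": 0.1, "f2": 1.5})  # f2 equals its constant
    e = mp.breakdown_explain(bundle, x, explain_class="pos", n_orderings=5, seed=0)
    c = e.contributions.set_index("feature")["contribution"]
    assert c["f2"] == pytest.approx(0.0, abs=1e-12)


def test_breakdown_unknown_feature_rejected(tuned_bundle):
    bundle, X = tuned_bundle
    inst = X.iloc[0].copy()
    inst["bogus"] = 1.0
    with pytest.raises(KeyError, match="bogus"):
        mp.breakdown_explain(bundle, inst)


def test_lime_recovers_linear_signs():
    bundle = _stub_bundle(weights=(0.05, -0.03, 0.0))
    x = pd.Series({"f0": 0.0, "f1": 0.0, "f2": 1.5})
    out = mp.lime_explain(bundle, x, explain_class="pos", n_perturbations=2000, seed=3)
    w = out.set_index("feature")["weight"]
    assert w["f0"] > 0 and out.set_index("feature").loc["f0", "direction"] == "supporting"
    assert w["f1"] < 0 and out.set_index("feature").loc["f1", "direction"] == "contradicting"


def test_lime_infinite_kernel_equals_global_least_squares():
    """Kernel width -> inf, no sparsity: exact WLS fit of the linear cloud.

    For a model exactly linear in the features the surrogate must recover
    the (standardized) coefficients w_j * sd_j to numerical precision,
    independent of the perturbation cloud.
    """
    weights = (0.04, -0.02, 0.0)
    bundle = _stub_bundle(weights=weights)
    sd = bundle.X_train.to_numpy().std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = pd.Series({"f0": 0.1, "f1": 0.2, "f2": 1.5})
    out = mp.lime_explain(
        bundle, x, explain_class="pos", n_perturbations=500,
        kernel_width=np.inf, n_features=None, seed=5,
    )
    got = out.set_index("feature")["weight"]
    for j, name in enumerate(bundle.feature_names):
        assert got[name] == pytest.approx(weights[j] * sd[j], abs=1e-9)


def test_lime_deterministic_given_seed(tuned_bundle):
    bundle, X = tuned_bundle
    a = mp.lime_explain(bundle, X.iloc[0], n_perturbations=300, seed=4)
    b = mp.lime_explain(bundle, X.iloc[0], n_perturbations=300, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_bundle_roundtrip(tmp_path, tuned_bundle):
    bundle, X = tuned_bundle
    path = str(tmp_path / "model.joblib")
    mp.save_bundle(bundle, path)
    back = mp.load_bundle(path)
    np.testing.assert_allclose(
        back.predict_proba(X.iloc[:5]), bundle.predict_proba(X.iloc[:5]), atol=1e-12
    )
    import json

    with open(path + ".json") as fh:
        schema = json.load(fh)
    assert schema["schema_version"] == 1
    assert schema["feature_names"] == bundle.feature_names
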