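"""Learner contract: class weights, fits, importances, determinism."""

import numpy as np
import pandas as pd
import pytest

from wristpa.exceptions import DegenerateLabelsError, InputError
from wristpa.features import FEATURE_NAMES
from wristpa.modeling import (
    LearnerSpec,
    compute_class_weights,
    default_grids,
    fit,
    lasso_alpha_grid,
    reduced_grids,
    sample_weights_from_labels,
)


def _X(rng, n):
    return pd.DataFrame(rng.normal(size=(n, 49)), columns=FEATURE_NAMES)


def _separable(rng, n=120):
    """Two classes separated by the first feature only."""
    X = _X(rng, n)
    y = np.where(np.arange(n) < n // 2, "a", "b")
    X.iloc[: n // 2, 0] = rng.normal(3.0, 0.1, size=n // 2)
    X.iloc[n // 2 :, 0] = rng.normal(-3.0, 0.1, size=n - n // 2)
    return X, y


@pytest.mark.parametrize(
    "labels,expected",
    [
        (["A"] * 50 + ["B"] * 50, {"A": 1.0, "B": 1.0}),
        (["A"] * 90 + ["B"] * 10, {"A": 100 / 180, "B": 5.0}),
        (["A", "B", "C", "C"], {"A": 4 / 3, "B": 4 / 3, "C": 4 / 6}),
    ],
)
def test_inverse_frequency_class_weights(labels, expected):
    weights = compute_class_weights(labels)
    assert weights == pytest.approx(expected)


def test_single_class_weights_rejected():
    with pytest.raises(DegenerateLabelsError):
        compute_class_weights(["A", "A", "A"])


@pytest.mark.parametrize("algorithm", ["decision_tree", "random_forest", "xgboost", "lasso"])
def test_separable_classification_reaches_perfect_training_f1(algorithm, rng):
    X, y = _separable(rng)
    spec = LearnerSpec(algorithm, "classification", seed=0)
    model = fit(spec, X, y, sample_weight=sample_weights_from_labels(y))
    assert (model.predict(X) == y).all()
    scores = model.predict_score(X, "a")
    assert scores.min() >= 0.0 and scores.max() <= 1.0
    assert scores[y == "a"].mean() > scores[y == "b"].mean()


@pytest.mark.parametrize("algorithm", ["decision_tree", "random_forest", "xgboost", "lasso"])
def test_refit_with_same_seed_is_deterministic(algorithm, rng):
    X = _X(rng, 150)
    y = rng.normal(size=150) + 2.0 + 3.0
    spec = LearnerSpec(algorithm, "regression", {"alpha": 0.01} if algorithm == "lasso" else {}, seed=7)
    p1 = fit(spec, X, y).predict(X)
    p2 = fit(spec, X, y).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_lasso_recovers_linear_coefficient(rng):
    X = _X(rng, 400)
    y = 2.0 * X["mvm"].to_numpy() + rng.normal(0, 1e-3, size=400)
    model = fit(LearnerSpec("lasso", "regression", {"alpha": 1e-6}, seed=0), X, y)
    coef = model.raw_coef
    # closed-form least squares as the oracle
    A = np.column_stack([X.to_numpy(), np.ones(400)])
    ls = np.linalg.lstsq(A, y, rcond=None)[0][:49]
    idx = FEATURE_NAMES.index("mvm")
    assert coef[idx] == pytest.approx(2.0, abs=1e-2)
    assert coef[idx] == pytest.approx(ls[idx], abs=1e-2)
    others = np.delete(coef, idx)
    assert np.abs(others).max() < 1e-2


@pytest.mark.parametrize("algorithm", ["decision_tree", "random_forest", "xgboost", "lasso"])
def test_importance_is_a_49_entry_distribution(algorithm, rng):
    X, y = _separable(rng)
    model = fit(LearnerSpec(algorithm, "classification", seed=0), X, y)
    imp = model.importance
    assert len(imp) == 49
    assert (imp >= 0).all()
    assert imp.sum() == pytest.approx(1.0)


def test_weighted_fit_matches_duplicated_data_for_trees(rng):
    X, y = _separable(rng, n=60)
    dup_X = pd.concat([X, X[y == "b"]], ignore_index=True)
    dup_y = np.concatenate([y, y[y == "b"]])
    w = np.where(y == "b", 2.0, 1.0)
    spec = LearnerSpec("decision_tree", "classification", {"max_depth": 3}, seed=0)
    grid = _X(rng, 200)
    pred_dup = fit(spec, dup_X, dup_y).predict(grid)
    pred_w = fit(spec, X, y, sample_weight=w).predict(grid)
    np.testing.assert_array_equal(pred_dup, pred_w)


@pytest.mark.parametrize("algorithm", ["decision_tree", "random_forest", "xgboost", "lasso"])
def test_regression_beats_constant_mean_predictor_in_sample(algorithm, rng):
    X = _X(rng, 200)
    y = X["sdvm"].to_numpy() * 1.5 + rng.normal(0, 0.1, 200) + 3.0
    hp = {"alpha": 1e-4} if algorithm == "lasso" else {}
    model = fit(LearnerSpec(algorithm, "regression", hp, seed=0), X, y)
    pred = model.predict(X)
    rmse_model = np.sqrt(np.mean((pred - y) ** 2))
    rmse_const = np.sqrt(np.mean((y.mean() - y) ** 2))
    assert rmse_model <= rmse_const


def test_non_finite_features_rejected(rng):
    X, y = _separable(rng, n=20)
    X.iloc[0, 0] = np.nan
    with pytest.raises(InputError):
        fit(LearnerSpec("decision_tree", "classification", seed=0), X, y)


def test_feature_order_is_enforced_at_prediction(rng):
    X, y = _separable(rng, n=40)
    model = fit(LearnerSpec("decision_tree", "classification", seed=0), X, y)
    shuffled = X[list(reversed(X.columns))]
    with pytest.raises(InputError):
        model.predict(shuffled)


def test_unsupported_spec_rejected():
    with pytest.raises(InputError):
        LearnerSpec("neural_net", "classification")
    with pytest.raises(InputError):
        LearnerSpec("lasso", "ranking")


def test_grids_cover_all_algorithms():
    for grids in (default_grids(), reduced_grids()):
        assert set(grids) == {"decision_tree", "random_forest", "xgboost", "lasso"}


def test_lasso_alpha_grid_descends_from_the_penalty_path(rng):
    X = _X(rng, 100)
    y = rng.normal(size=100)
    alphas = lasso_alpha_grid(X, y, n_points=50)
    assert len(alphas) == 50
    assert alphas[0] > alphas[-1] > 0
    assert alphas[0] == pytest.approx(alphas[-1] * 1e3, rel=1e-6)
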