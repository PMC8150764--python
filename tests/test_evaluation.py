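"""Metrics, fold assignment, grouped nested CV and importance reports."""

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics
from hypothesis import given
from hypothesis import strategies as st

from wristpa.evaluation import (
    ActivityTaskModel,
    assign_folds,
    auc,
    balanced_accuracy,
    f1_score,
    macro_f1,
    nested_cv,
    rmse,
    top_features,
)
from wristpa.exceptions import InputError, UndefinedMetricError
from wristpa.features import FEATURE_NAMES
from wristpa.labels import TaskDataset, build_task_dataset
from wristpa.modeling import reduced_grids


# --- fold assignment --------------------------------------------------------

def test_ten_participants_make_five_folds_of_two():
    folds = assign_folds([f"P{i}" for i in range(10)], k=5, seed=0)
    sizes = pd.Series(folds).value_counts()
    assert sorted(sizes) == [2, 2, 2, 2, 2]


def test_fold_sizes_differ_by_at_most_one():
    folds = assign_folds([f"P{i}" for i in range(13)], k=5, seed=3)
    sizes = pd.Series(folds).value_counts()
    assert sizes.max() - sizes.min() <= 1


def test_too_few_participants_rejected():
    with pytest.raises(InputError):
        assign_folds(["a", "b", "c", "d"], k=5)


# --- metrics ----------------------------------------------------------------

@pytest.mark.parametrize("tp,fp,fn,expected", [(10, 0, 0, 1.0), (1, 1, 1, 0.5), (0, 5, 5, 0.0)])
def test_f1_closed_forms(tp, fp, fn, expected):
    assert f1_score(tp, fp, fn) == pytest.approx(expected)


@pytest.mark.parametrize(
    "counts,expected", [((10, 0, 10, 0), 1.0), ((10, 10, 0, 0), 0.5), ((8, 4, 6, 2), 0.7)]
)
def test_balanced_accuracy_closed_forms(counts, expected):
    tp, fp, tn, fn = counts
    assert balanced_accuracy(tp, fp, tn, fn) == pytest.approx(expected)


def test_balanced_accuracy_undefined_without_both_classes():
    with pytest.raises(UndefinedMetricError):
        balanced_accuracy(5, 0, 0, 0)


def test_auc_examples():
    assert auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], [True, False, True, False]) == 0.5
    # brute force over pairs: one win, one loss of two (+,-) pairs
    assert auc([0.9, 0.8, 0.3], [True, False, True]) == 0.5
    with pytest.raises(UndefinedMetricError):
        auc([0.1, 0.2], [True, True])


@given(seed=st.integers(0, 500))
def test_auc_matches_sklearn_rank_implementation(seed):
    rng = np.random.default_rng(seed)
    scores = rng.choice(np.linspace(0, 1, 11), size=30)  # ties included
    labels = rng.uniform(size=30) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    assert auc(scores, labels) == pytest.approx(
        sklearn.metrics.roc_auc_score(labels, scores)
    )


@pytest.mark.parametrize(
    "pred,obs,expected",
    [(([1.0, 2.0]), ([1.0, 2.0]), 0.0), (([2.0, 1.0]), ([1.0, 2.0]), 1.0), (([4.0, 5.0]), ([1.0, 1.0]), np.sqrt(12.5))],
)
def test_rmse_closed_forms(pred, obs, expected):
    assert rmse(pred, obs) == pytest.approx(expected)


def test_macro_f1_is_unweighted_mean():
    assert macro_f1([1.0, 1.0, 1.0]) == 1.0
    assert macro_f1([0.2, 0.8]) == pytest.approx(0.5)
    assert macro_f1([0.37] * 33) == pytest.approx(0.37)
    with pytest.raises(InputError):
        macro_f1([])


# --- nested CV --------------------------------------------------------------

@pytest.fixture(scope="module")
def binary_dataset(request):
    small_features = request.getfixturevalue("small_features")
    small_cohort = request.getfixturevalue("small_cohort")
    return build_task_dataset(
        small_features, small_cohort.roster, "type_binary", target_name="sedentary"
    )


def test_nested_cv_is_deterministic(binary_dataset):
    r1 = nested_cv(binary_dataset, "decision_tree", grids=reduced_grids(), seed=11)
    r2 = nested_cv(binary_dataset, "decision_tree", grids=reduced_grids(), seed=11)
    assert r1.summary().equals(r2.summary())
    assert [f.chosen_hyperparams for f in r1.folds] == [f.chosen_hyperparams for f in r2.folds]


def test_nested_cv_groups_participants_without_leakage(binary_dataset):
    res = nested_cv(binary_dataset, "decision_tree", grids=reduced_grids(), seed=2)
    all_pids = set(binary_dataset.groups)
    seen = []
    for fold in res.folds:
        seen.extend(fold.test_participants)
        assert set(fold.test_participants) <= all_pids
    assert sorted(seen) == sorted(all_pids)  # each participant tested exactly once
    assert len(res.folds) == 5


def test_nested_cv_metrics_are_bounded_and_confusion_totals_match(binary_dataset):
    res = nested_cv(binary_dataset, "decision_tree", grids=reduced_grids(), seed=2)
    for name in ("f1", "auc", "balanced_accuracy", "accuracy"):
        for v in res.metric_values(name):
            assert 0.0 <= v <= 1.0
    assert res.confusion.to_numpy().sum() == binary_dataset.n_windows
    # row totals equal per-class window counts
    counts = pd.Series(binary_dataset.y).value_counts()
    for cls in res.confusion.index:
        assert res.confusion.loc[cls].sum() == counts[cls]


def test_model_results_api_summary(binary_dataset):
    model = ActivityTaskModel(binary_dataset, "decision_tree", grids=reduced_grids())
    res = model.fit(seed=11, refit_final=True)
    summ = res.summary()
    assert {"f1", "auc", "balanced_accuracy", "accuracy"} <= set(summ.index)
    assert (summ["n_folds"] == 5).all()
    assert res.final_model is not None
    assert "Nested CV" in str(res)


def _single_signal_dataset(rng, informative="sdvm"):
    """Binary task where only one feature carries signal."""
    n_pid, wins = 10, 12
    rows, y, groups = [], [], []
    for p in range(n_pid):
        positive = p % 2 == 0
        for _ in range(wins):
            row = rng.normal(size=49)
            row[FEATURE_NAMES.index(informative)] = 5.0 if positive else -5.0
            rows.append(row)
            y.append("busy" if positive else "non_busy")
            groups.append(f"P{p}")
    X = pd.DataFrame(rows, columns=FEATURE_NAMES)
    return TaskDataset(
        kind="individual_multiclass", target_name=None, age_stratum="all",
        X=X, y=np.array(y), groups=np.array(groups),
    )


def test_top_features_rank_the_informative_feature_first(rng):
    ds = _single_signal_dataset(rng)
    res = nested_cv(ds, "decision_tree", grids=reduced_grids(), seed=4)
    top = top_features(res, n=15)
    assert len(top) == 15
    assert top.index[0] == "sdvm"
    full = top_features(res, n=49)
    assert full.sum() == pytest.approx(1.0)
    with pytest.raises(InputError):
        top_features(res, n=50)
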