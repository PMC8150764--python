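"""Participant-grouped 5-fold nested cross-validation and reported metrics.

Participants (never windows) are randomly assigned to folds, so all of a
participant's windows share a fold and no individual contributes to both
training and testing — this is asserted on every run. The outer loop
estimates generalisation; for each outer fold an inner (k-1)-fold grouped CV
over the outer-training participants selects hyperparameters (highest F1 for
classification, lowest RMSE for regression), the model is refitted on the
full outer-training set with class weights recomputed on it, and metrics are
computed on the held-out fold.

The primary API follows the model/results pattern:

>>> model = ActivityTaskModel(dataset, algorithm="xgboost")
>>> res = model.fit(seed=0)
>>> print(res.summary())

``nested_cv`` is the equivalent functional entry point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import modeling
from .exceptions import InputError, UndefinedMetricError
from .features import FEATURE_NAMES
from .labels import TaskDataset

logger = logging.getLogger(__name__)

CLASSIFICATION_METRICS = ("f1", "auc", "balanced_accuracy", "accuracy")


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

def assign_folds(participant_ids, k: int = 5, seed: int = 0) -> dict:
    """Random size-balanced partition of participants into k folds."""
    pids = sorted(set(participant_ids))
    if len(pids) < k:
        raise InputError(f"need at least {k} participants, got {len(pids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    return {pids[j]: i % k for i, j in enumerate(order)}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 * precision * recall / (precision + recall); 0 when undefined."""
    if min(tp, fp, fn) < 0:
        raise InputError("counts must be nonnegative")
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """(sensitivity + specificity) / 2; requires both classes present."""
    if min(tp, fp, tn, fn) < 0:
        raise InputError("counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("balanced accuracy needs both classes present")
    return (tp / (tp + fn) + tn / (tn + fp)) / 2.0


def auc(scores, labels, positive_label=True) -> float:
    """Area under the ROC curve via the rank statistic.

    Equals P(score+ > score-) + 0.5 * P(tie), the trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def rmse(predicted, observed) -> float:
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) == 0 or len(predicted) != len(observed):
        raise InputError("predicted and observed must be non-empty and aligned")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def macro_f1(per_class_f1) -> float:
    values = np.asarray(list(per_class_f1), dtype=float)
    if len(values) == 0:
        raise InputError("macro F1 of an empty list is undefined")
    return float(values.mean())


def _binary_counts(y_true, y_pred, positive_label) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_pred == positive_label) & (y_true == positive_label)))
    fp = int(np.sum((y_pred == positive_label) & (y_true != positive_label)))
    tn = int(np.sum((y_pred != positive_label) & (y_true != positive_label)))
    fn = int(np.sum((y_pred != positive_label) & (y_true == positive_label)))
    return tp, fp, tn, fn


def per_class_f1(y_true, y_pred, classes) -> dict:
    out = {}
    for c in classes:
        tp, fp, _, fn = _binary_counts(y_true, y_pred, c)
        out[c] = f1_score(tp, fp, fn)
    return out


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    fold_index: int
    test_participants: list
    chosen_hyperparams: dict
    inner_score: float
    metrics: dict
    per_class_f1: dict | None = None


@dataclass
class NestedCVResults:
    """Per-fold and aggregate results of one grouped nested-CV run."""

    kind: str
    target_name: str | None
    age_stratum: str
    algorithm: str
    k: int
    seed: int
    n_windows: int
    n_participants: int
    folds: list[FoldRecord]
    confusion: pd.DataFrame | None
    importance_mean: pd.Series
    best_hyperparams: dict
    final_model: modeling.FittedModel | None = None

    def metric_values(self, metric: str) -> list[float]:
        return [f.metrics[metric] for f in self.folds if f.metrics.get(metric) is not None]

    def summary(self) -> pd.DataFrame:
        """Mean and sd of each metric over the outer folds."""
        metrics = sorted({m for f in self.folds for m in f.metrics})
        rows = []
        for m in metrics:
            vals = self.metric_values(m)
            rows.append(
                {
                    "metric": m,
                    "mean": float(np.mean(vals)) if vals else math.nan,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
                    "n_folds": len(vals),
                }
            )
        return pd.DataFrame(rows).set_index("metric")

    def __str__(self) -> str:
        head = (
            f"Nested CV ({self.k}-fold, grouped by participant)\n"
            f"task: {self.kind}"
            + (f" [{self.target_name}]" if self.target_name else "")
            + f", stratum: {self.age_stratum}, algorithm: {self.algorithm}\n"
            f"windows: {self.n_windows}, participants: {self.n_participants}\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v:.4f}")


def _inner_metric(task: str):
    return "f1" if task == "classification" else "neg_rmse"


def _evaluate_config(
    dataset: TaskDataset,
    algorithm: str,
    task: str,
    hyperparams: dict,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    seed: int,
    positive_label,
):
    """Fit on train rows, score on test rows; returns (score, model)."""
    spec = modeling.LearnerSpec(algorithm=algorithm, task=task, hyperparams=hyperparams, seed=seed)
    X_train, y_train = dataset.X[train_mask], dataset.y[train_mask]
    weights = None
    if task == "classification":
        weights = modeling.sample_weights_from_labels(y_train)
    model = modeling.fit(spec, X_train, y_train, sample_weight=weights)
    X_test, y_test = dataset.X[test_mask], dataset.y[test_mask]
    y_pred = model.predict(X_test)
    if task == "regression":
        return -rmse(y_pred, y_test), model
    if positive_label is not None:
        tp, fp, _, fn = _binary_counts(y_test, y_pred, positive_label)
        return f1_score(tp, fp, fn), model
    return macro_f1(per_class_f1(y_test, y_pred, np.unique(dataset.y)).values()), model


def nested_cv(
    dataset: TaskDataset,
    algorithm: str,
    grids: dict | list | None = None,
    k: int = 5,
    seed: int = 0,
    refit_final: bool = False,
) -> NestedCVResults:
    """Grouped nested cross-validation of one learner family on one task.

    ``grids`` may be the full per-algorithm grid dict, a list of
    hyperparameter dicts for this algorithm, or None (package defaults; for
    lasso the penalty grid is then derived from each outer-training set's
    penalty path).
    """
    task = "regression" if dataset.is_regression else "classification"
    if isinstance(grids, dict) or grids is None:
        grid = (grids or modeling.default_grids()).get(algorithm)
    else:
        grid = grids
    positive_label = dataset.target_name if dataset.kind.endswith("_binary") else None
    fold_of = assign_folds(np.unique(dataset.groups), k=k, seed=seed)
    row_fold = np.asarray([fold_of[p] for p in dataset.groups])
    classes = np.unique(dataset.y) if task == "classification" else None

    fold_records: list[FoldRecord] = []
    confusion = (
        pd.DataFrame(0, index=classes, columns=classes) if task == "classification" else None
    )
    importances = []
    for i in range(k):
        test_mask = row_fold == i
        train_mask = ~test_mask
        train_pids = set(dataset.groups[train_mask])
        test_pids = set(dataset.groups[test_mask])
        assert not train_pids & test_pids, "participant leakage across outer folds"
        if not test_mask.any():
            logger.warning("outer fold %d has no windows; skipped", i)
            continue

        fold_grid = grid
        if fold_grid is None:  # data-driven lasso penalty path
            alphas = modeling.lasso_alpha_grid(dataset.X[train_mask], dataset.y[train_mask])
            fold_grid = [{"alpha": a} for a in alphas]

        # inner loop: (k-1)-fold grouped CV over the outer-training participants
        inner_fold_of = assign_folds(sorted(train_pids), k=k - 1, seed=seed * 9973 + i + 1)
        inner_row_fold = np.asarray(
            [inner_fold_of.get(p, -1) for p in dataset.groups]
        )
        best_score, best_params = -np.inf, fold_grid[0]
        for params in fold_grid:
            scores = []
            for j in range(k - 1):
                val_mask = train_mask & (inner_row_fold == j)
                fit_mask = train_mask & (inner_row_fold != j)
                if not val_mask.any() or not fit_mask.any():
                    continue
                try:
                    score, _ = _evaluate_config(
                        dataset, algorithm, task, params, fit_mask, val_mask,
                        seed=seed, positive_label=positive_label,
                    )
                except Exception:  # degenerate inner split (single class)
                    continue
                scores.append(score)
            mean_score = float(np.mean(scores)) if scores else -np.inf
            if mean_score > best_score:
                best_score, best_params = mean_score, params

        # refit on full outer-training set, evaluate on the held-out fold
        _, model = _evaluate_config(
            dataset, algorithm, task, best_params, train_mask, train_mask,
            seed=seed, positive_label=positive_label,
        )
        X_test, y_test = dataset.X[test_mask], dataset.y[test_mask]
        y_pred = model.predict(X_test)
        metrics: dict[str, float | None] = {}
        fold_pcf = None
        if task == "regression":
            metrics["rmse"] = rmse(y_pred, y_test)
        else:
            metrics["accuracy"] = float(np.mean(y_pred == y_test))
            if positive_label is not None:
                tp, fp, tn, fn = _binary_counts(y_test, y_pred, positive_label)
                metrics["f1"] = f1_score(tp, fp, fn)
                try:
                    metrics["balanced_accuracy"] = balanced_accuracy(tp, fp, tn, fn)
                except UndefinedMetricError:
                    metrics["balanced_accuracy"] = None
                    logger.warning("fold %d: balanced accuracy undefined (class absent)", i)
                try:
                    scores_pos = model.predict_score(X_test, positive_label)
                    metrics["auc"] = auc(scores_pos, y_test, positive_label)
                except UndefinedMetricError:
                    metrics["auc"] = None
                    logger.warning("fold %d: AUC undefined (class absent)", i)
            else:
                fold_pcf = per_class_f1(y_test, y_pred, classes)
                metrics["f1"] = macro_f1(fold_pcf.values())
                present = np.isin(classes, np.unique(y_test))
                recalls = []
                for c in np.asarray(classes)[present]:
                    tp = int(np.sum((y_pred == c) & (y_test == c)))
                    recalls.append(tp / int(np.sum(y_test == c)))
                metrics["balanced_accuracy"] = float(np.mean(recalls))
            for true_c, pred_c in zip(y_test, y_pred):
                confusion.loc[true_c, pred_c] += 1
        importances.append(model.importance)
        fold_records.append(
            FoldRecord(
                fold_index=i,
                test_participants=sorted(test_pids),
                chosen_hyperparams=best_params,
                inner_score=best_score,
                metrics=metrics,
                per_class_f1=fold_pcf,
            )
        )

    imp_mean = pd.concat(importances, axis=1).mean(axis=1)
    imp_mean = imp_mean / imp_mean.sum()
    best_overall = max(fold_records, key=lambda f: f.inner_score).chosen_hyperparams
    final_model = None
    if refit_final:
        spec = modeling.LearnerSpec(algorithm=algorithm, task=task, hyperparams=best_overall, seed=seed)
        weights = modeling.sample_weights_from_labels(dataset.y) if task == "classification" else None
        final_model = modeling.fit(spec, dataset.X, dataset.y, sample_weight=weights)
    return NestedCVResults(
        kind=dataset.kind,
        target_name=dataset.target_name,
        age_stratum=dataset.age_stratum,
        algorithm=algorithm,
        k=k,
        seed=seed,
        n_windows=dataset.n_windows,
        n_participants=dataset.n_participants,
        folds=fold_records,
        confusion=confusion,
        importance_mean=imp_mean,
        best_hyperparams=best_overall,
        final_model=final_model,
    )


def top_features(result: NestedCVResults, n: int = 15) -> pd.Series:
    """Top-n features by fold-averaged importance (ties: canonical order)."""
    if n > len(FEATURE_NAMES):
        raise InputError(f"n must be at most {len(FEATURE_NAMES)}")
    imp = result.importance_mean / result.importance_mean.sum()
    order = sorted(
        imp.index, key=lambda name: (-imp[name], FEATURE_NAMES.index(name))
    )
    return imp.loc[order[:n]]


class ActivityTaskModel:
    """Model object tying one task dataset to one learner family.

    ``fit`` runs participant-grouped nested cross-validation and returns a
    :class:`NestedCVResults` carrying per-fold metrics, their mean and sd,
    the pooled confusion matrix, fold-averaged feature importances and the
    hyperparameters with the best inner score (optionally refitted on all
    data as ``final_model``).
    """

    def __init__(self, dataset: TaskDataset, algorithm: str, grids=None, k: int = 5):
        if algorithm not in modeling.ALGORITHMS:
            raise InputError(f"unknown algorithm {algorithm!r}")
        self.dataset = dataset
        self.algorithm = algorithm
        self.grids = grids
        self.k = k

    @classmethod
    def from_dataframe(
        cls,
        windows: pd.DataFrame,
        roster: pd.DataFrame,
        kind: str,
        algorithm: str,
        target_name: str | None = None,
        age_stratum: str = "all",
        mapping: dict | None = None,
        scheme=None,
        grids=None,
        k: int = 5,
    ) -> "ActivityTaskModel":
        from .labels import build_task_dataset

        dataset = build_task_dataset(
            windows, roster, kind, target_name=target_name, age_stratum=age_stratum,
            mapping=mapping, scheme=scheme,
        )
        return cls(dataset, algorithm, grids=grids, k=k)

    def fit(self, seed: int = 0, refit_final: bool = False) -> NestedCVResults:
        return nested_cv(
            self.dataset, self.algorithm, grids=self.grids, k=self.k, seed=seed,
            refit_final=refit_final,
        )
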