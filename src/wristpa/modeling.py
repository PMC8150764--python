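"""Four learner families behind one fit/predict contract.

Decision tree, random forest and L1-penalised linear models are backed by
scikit-learn; gradient boosting by xgboost. ``lasso`` means L1 linear
regression for regression tasks and L1-penalised logistic regression for
classification. Class imbalance is handled uniformly by per-row sample
weights, inverse to the class frequencies in the training data
(``w_c = N / (K * N_c)``).

L1 models are fitted on standardised features (the 49 features span several
orders of magnitude); coefficients in original feature units are exposed as
``FittedModel.raw_coef``. Feature importance is the learner's impurity/gain
importance for tree-based models and the normalised absolute (standardised)
coefficient for L1 models, rescaled to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from xgboost import XGBClassifier, XGBRegressor

from .exceptions import DegenerateLabelsError, InputError
from .features import FEATURE_NAMES

ALGORITHMS = ("decision_tree", "random_forest", "xgboost", "lasso")
TASKS = ("classification", "regression")


@dataclass(frozen=True)
class LearnerSpec:
    """One learner instance: algorithm, task, hyperparameters, seed."""

    algorithm: str
    task: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InputError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in TASKS:
            raise InputError(f"unknown task {self.task!r}")


def compute_class_weights(labels) -> dict:
    """Inverse-frequency class weights: ``w_c = N / (K * N_c)``."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelsError("need at least two classes to weight")
    n, k = len(labels), len(classes)
    return {c: n / (k * nc) for c, nc in zip(classes, counts)}


def sample_weights_from_labels(labels) -> np.ndarray:
    """Per-row weights carrying the row's class weight."""
    weights = compute_class_weights(labels)
    return np.asarray([weights[c] for c in np.asarray(labels)], dtype=float)


def _build_estimator(spec: LearnerSpec, n_samples: int):
    hp = dict(spec.hyperparams)
    if spec.algorithm == "decision_tree":
        cls = DecisionTreeClassifier if spec.task == "classification" else DecisionTreeRegressor
        return cls(max_depth=hp.get("max_depth"), random_state=spec.seed)
    if spec.algorithm == "random_forest":
        cls = RandomForestClassifier if spec.task == "classification" else RandomForestRegressor
        return cls(
            n_estimators=hp.get("n_estimators", 100),
            max_features=hp.get("max_features", "sqrt"),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "xgboost":
        cls = XGBClassifier if spec.task == "classification" else XGBRegressor
        return cls(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 6),
            learning_rate=hp.get("learning_rate", 0.3),
            tree_method="hist",
            n_jobs=1,
            random_state=spec.seed,
            verbosity=0,
        )
    # lasso
    alpha = hp.get("alpha", 1e-3)
    if spec.task == "regression":
        model = Lasso(alpha=alpha, max_iter=50_000, random_state=spec.seed)
    else:
        # sklearn logistic minimises sum(loss) + |w|/C; the lasso objective
        # mean(loss) + alpha*|w| corresponds to C = 1 / (n * alpha)
        model = LogisticRegression(
            penalty="l1", C=1.0 / (n_samples * alpha), solver="liblinear", random_state=spec.seed
        )
    return Pipeline([("scale", StandardScaler()), ("model", model)])


@dataclass
class FittedModel:
    """A fitted learner bound to the canonical feature order."""

    spec: LearnerSpec
    feature_order: list[str]
    estimator: object
    classes: np.ndarray | None = None  # classification only

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_order:
            raise InputError("feature columns do not match the training order")
        values = X.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InputError("non-finite feature values")
        return values

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        values = self._check(X)
        pred = self.estimator.predict(values)
        if self.classes is not None and np.issubdtype(np.asarray(pred).dtype, np.integer):
            pred = self.classes[pred]
        return np.asarray(pred)

    def predict_score(self, X: pd.DataFrame, positive_label) -> np.ndarray:
        """Probability-like score in [0, 1] for one class (for AUC)."""
        if self.classes is None:
            raise InputError("scores are defined for classifiers only")
        values = self._check(X)
        proba = self.estimator.predict_proba(values)
        idx = int(np.flatnonzero(self.classes == positive_label)[0])
        return np.asarray(proba[:, idx], dtype=float)

    @property
    def raw_coef(self) -> np.ndarray:
        """L1-model coefficients in original feature units."""
        if self.spec.algorithm != "lasso":
            raise InputError("raw_coef is defined for lasso models only")
        scaler = self.estimator.named_steps["scale"]
        model = self.estimator.named_steps["model"]
        coef = np.ravel(model.coef_)
        return coef / scaler.scale_

    @property
    def importance(self) -> pd.Series:
        """Nonnegative per-feature importance scaled to sum to one."""
        if self.spec.algorithm == "lasso":
            raw = np.abs(np.ravel(self.estimator.named_steps["model"].coef_))
        else:
            raw = np.asarray(self.estimator.feature_importances_, dtype=float)
        total = raw.sum()
        if total <= 0:
            raw = np.ones_like(raw)
            total = raw.sum()
        return pd.Series(raw / total, index=self.feature_order)


def fit(
    spec: LearnerSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> FittedModel:
    """Fit one learner; deterministic given the spec's seed."""
    if list(X.columns) != FEATURE_NAMES:
        raise InputError("X must carry the 49 features in canonical order")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("non-finite feature values")
    y = np.asarray(y)
    if sample_weight is not None and len(sample_weight) != len(y):
        raise InputError("sample_weight must align with y")
    estimator = _build_estimator(spec, n_samples=len(y))
    classes = None
    if spec.task == "classification":
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateLabelsError("need at least two classes")
    y_fit = y
    if spec.algorithm == "xgboost" and spec.task == "classification":
        y_fit = np.searchsorted(classes, y)  # xgboost wants integer labels
    if isinstance(estimator, Pipeline):
        kwargs = {"model__sample_weight": sample_weight} if sample_weight is not None else {}
        estimator.fit(values, y_fit, **kwargs)
    else:
        estimator.fit(values, y_fit, sample_weight=sample_weight)
    fitted = FittedModel(
        spec=spec, feature_order=list(X.columns), estimator=estimator, classes=classes
    )
    return fitted


def lasso_alpha_grid(
    X: pd.DataFrame, y: np.ndarray, n_points: int = 50, ratio: float = 1e-3
) -> list[float]:
    """Logarithmic penalty grid anchored at the data's penalty path.

    The largest alpha is the smallest penalty that zeroes every coefficient
    of the standardised problem (``max |X'ᵀ y'| / n``); the grid descends
    log-linearly to ``ratio`` times that value.
    """
    values = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    yv = np.asarray(y)
    if yv.dtype.kind in "OUS":  # classification: +/-1 coding around the mean
        yv = (yv == np.unique(yv)[0]).astype(float)
    yc = yv - yv.mean()
    alpha_max = float(np.max(np.abs(values.T @ yc)) / len(yc))
    alpha_max = max(alpha_max, 1e-6)
    return list(np.logspace(np.log10(alpha_max), np.log10(alpha_max * ratio), n_points))


def default_grids() -> dict[str, list[dict] | None]:
    """Conventional hyperparameter grids (the study reports none).

    ``None`` for lasso means the penalty grid is derived from the training
    data's penalty path at tuning time (50 log-spaced points).
    """
    return {
        "decision_tree": [{"max_depth": d} for d in (3, 5, 10, None)],
        "random_forest": [
            {"n_estimators": n, "max_features": mf}
            for n in (100, 300)
            for mf in ("sqrt", 1.0 / 3.0)
        ],
        "xgboost": [
            {"max_depth": d, "learning_rate": lr, "n_estimators": n}
            for d in (3, 6)
            for lr in (0.1, 0.3)
            for n in (100, 300)
        ],
        "lasso": None,
    }


def reduced_grids() -> dict[str, list[dict] | None]:
    """Small grids for desk-scale experiment-grid runs."""
    return {
        "decision_tree": [{"max_depth": d} for d in (3, None)],
        "random_forest": [{"n_estimators": 100, "max_features": "sqrt"}],
        "xgboost": [{"max_depth": 3, "learning_rate": 0.3, "n_estimators": 50}],
        "lasso": [{"alpha": a} for a in np.logspace(-1, -4, 8)],
    }
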