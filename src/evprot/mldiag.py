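"""Imbalanced-class diagnostic-classifier framework.

Mirrors a three-step learning framework for tiny, unbalanced cohorts:

1. *Oversampling*: the minority class is expanded by SMOTE-style
   interpolation between minority nearest neighbours,
   ``x_new = x_i + u (x_nn - x_i)`` with ``u ~ Uniform(0, 1)``, up to a
   target count (default 9, giving a 10 + 9 = 19-sample dataset).
2. *Parameter search*: per classifier family, grid search with stratified
   twofold cross-validation on a seeded 13/6 stratified train/test split.
3. *Feature selection*: recursive feature elimination with cross-validation
   for families exposing importances or coefficients; families without them
   keep the full feature set.

Accuracy is reported on the held-out test set and on external validation
sets (drug-naive and drug-exposed patient samples from the other measurement
batch); the best model is the one with the highest mean validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFECV
from sklearn.linear_model import Perceptron
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "MLExperimentConfig",
    "smote_oversample",
    "split_train_test",
    "default_model_zoo",
    "train_evaluate",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class MLExperimentConfig:
    """Configuration of the diagnostic-classifier experiment."""

    seed: int = 111
    oversample_k_neighbors: int | None = None   # None -> min(5, minority-1)
    target_minority_count: int = 9
    train_count: int = 13
    test_count: int = 6
    cv_folds: int = 2
    rfe_step: float = 0.2
    model_names: tuple = (
        "random_forest", "gradient_boosting", "adaboost", "extra_trees",
        "decision_tree", "xgboost", "perceptron",
    )

    def validate(self, n_total: int) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.train_count + self.test_count != n_total:
            raise ValueError(
                f"train_count + test_count ({self.train_count + self.test_count}) "
                f"must equal dataset size after oversampling ({n_total})"
            )


def smote_oversample(features: np.ndarray, labels: Sequence,
                     target_minority_count: int = 9,
                     k_neighbors: int | None = None,
                     seed: int = 111) -> tuple:
    """SMOTE-style minority oversampling by nearest-neighbour interpolation.

    Synthetic points are ``x_i + u (x_nn - x_i)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` a random one of the k nearest minority neighbours of
    ``x_i``.  k adapts to ``min(5, minority_size - 1)`` when unspecified,
    since library defaults would fail at very small minority sizes.
    Majority samples are untouched.  Returns ``(features, labels)`` with the
    synthetic rows appended.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("feature matrix must be complete (no missing values)")
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[counts.argmin()]
    minority_idx = np.flatnonzero(y == minority)
    n_min = minority_idx.size
    if n_min < 2:
        raise ValueError("minority class needs >= 2 members for interpolation")
    n_new = target_minority_count - n_min
    if n_new <= 0:
        return X, y
    k = k_neighbors if k_neighbors is not None else min(5, n_min - 1)
    k = min(k, n_min - 1)
    Xm = X[minority_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]   # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x_i = Xm[base]
    x_nn = Xm[neigh[base, pick]]
    synthetic = x_i + u[:, None] * (x_nn - x_i)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def split_train_test(features: np.ndarray, labels: Sequence,
                     config: MLExperimentConfig | None = None) -> tuple:
    """Seeded stratified split into (train_idx, test_idx).

    Test-set class counts follow largest-remainder proportional allocation
    with at least one sample per class in each partition; for the default
    10 + 9 dataset this puts an equal number of each class in the test set
    (3 + 3) and 13 samples in training.
    """
    cfg = config or MLExperimentConfig()
    y = np.asarray(labels)
    cfg.validate(y.size)
    rng = np.random.default_rng(cfg.seed)
    classes, counts = np.unique(y, return_counts=True)
    exact = cfg.test_count * counts / y.size
    n_test = np.floor(exact).astype(int)
    n_test = np.maximum(n_test, 1)
    remainder = exact - np.floor(exact)
    while n_test.sum() < cfg.test_count:
        n_test[np.argmax(remainder)] += 1
        remainder[np.argmax(remainder)] = -1
    while n_test.sum() > cfg.test_count:
        order = np.argsort(remainder)
        for i in order:
            if n_test[i] > 1:
                n_test[i] -= 1
                break
    test_idx = []
    for cls, nt in zip(classes, n_test):
        idx = np.flatnonzero(y == cls)
        if nt >= idx.size:
            raise ValueError(f"class {cls!r} too small for the requested split")
        test_idx.extend(rng.permutation(idx)[:nt])
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(y.size), test_idx)
    return train_idx, test_idx


def default_model_zoo(seed: int = 111, extra: Mapping | None = None) -> dict:
    """Named classifier families with small hyperparameter grids."""
    zoo = {
        "random_forest": (
            RandomForestClassifier(n_estimators=50, random_state=seed),
            {"max_depth": [None, 3]},
        ),
        "gradient_boosting": (
            GradientBoostingClassifier(n_estimators=50, random_state=seed),
            {"learning_rate": [0.1, 0.3]},
        ),
        "adaboost": (
            AdaBoostClassifier(random_state=seed),
            {"n_estimators": [25, 50]},
        ),
        "extra_trees": (
            ExtraTreesClassifier(n_estimators=50, random_state=seed),
            {"max_depth": [None, 3]},
        ),
        "decision_tree": (
            DecisionTreeClassifier(random_state=seed),
            {"max_depth": [None, 3]},
        ),
        # exact greedy split finding: histogram binning places thresholds on
        # data points, which generalises poorly at these tiny sample sizes
        "xgboost": (
            XGBClassifier(n_estimators=50, random_state=seed,
                          eval_metric="logloss", tree_method="exact"),
            {"max_depth": [2, 4]},
        ),
        # linear model gets feature standardisation (margin geometry depends
        # on scale); trees are scale-invariant and stay raw
        "perceptron": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", Perceptron(random_state=seed))]),
            {"clf__alpha": [1e-4, 1e-3]},
            "named_steps.clf.coef_",
        ),
    }
    if extra:
        zoo.update(extra)
    return zoo


def _accuracy(model, X, y, feature_mask=None) -> float:
    if feature_mask is not None:
        X = X[:, feature_mask]
    return float((model.predict(X) == y).mean())


def train_evaluate(X_train: np.ndarray, y_train: Sequence,
                   X_test: np.ndarray, y_test: Sequence,
                   validations: Mapping,
                   config: MLExperimentConfig | None = None,
                   model_zoo: Mapping | None = None) -> pd.DataFrame:
    """Grid search + RFECV + external validation per classifier family.

    ``validations`` maps set name -> (X, y).  Returns one row per family:
    selected feature count, test accuracy, per-validation accuracies and
    their mean; ``result.attrs['best_model']`` names the family with the
    highest mean validation accuracy, ``attrs['selected_features']`` holds
    per-family selected feature index arrays.
    """
    cfg = config or MLExperimentConfig()
    zoo = model_zoo or default_model_zoo(cfg.seed)
    zoo = {k: v for k, v in zoo.items() if k in cfg.model_names or k not in
           default_model_zoo(cfg.seed)}
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels are single-class")
    cv = StratifiedKFold(n_splits=cfg.cv_folds)
    rows = []
    selected: dict = {}
    for name, spec in zoo.items():
        base, grid = spec[0], spec[1]
        importance_getter = spec[2] if len(spec) > 2 else "auto"
        search = GridSearchCV(clone(base), grid, cv=cv, scoring="accuracy")
        search.fit(X_train, y_train)
        best = search.best_estimator_
        mask = np.ones(X_train.shape[1], dtype=bool)
        try:
            rfe = RFECV(clone(best), cv=cv, scoring="accuracy",
                        step=cfg.rfe_step, min_features_to_select=1,
                        importance_getter=importance_getter)
            rfe.fit(X_train, y_train)
            mask = rfe.support_
            model = rfe.estimator_
        except (ValueError, AttributeError, RuntimeError) as exc:
            logger.info("family %s skips RFE (%s); full feature set kept",
                        name, exc)
            model = clone(best).fit(X_train, y_train)
        selected[name] = np.flatnonzero(mask)
        row = {
            "model": name,
            "n_features": int(mask.sum()),
            "accuracy_test": _accuracy(model, X_test, y_test, mask),
        }
        val_accs = []
        for vname, (Xv, yv) in validations.items():
            acc = _accuracy(model, np.asarray(Xv, dtype=float),
                            np.asarray(yv), mask)
            row[f"accuracy_{vname}"] = acc
            val_accs.append(acc)
        row["accuracy_validation_mean"] = float(np.mean(val_accs)) if val_accs \
            else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("model")
    if len(out) and out["accuracy_validation_mean"].notna().any():
        out.attrs["best_model"] = out["accuracy_validation_mean"].idxmax()
    out.attrs["selected_features"] = selected
    return out


def run_experiment(features: np.ndarray, labels: Sequence,
                   validations: Mapping,
                   config: MLExperimentConfig | None = None,
                   model_zoo: Mapping | None = None) -> pd.DataFrame:
    """Full pipeline: oversample -> stratified split -> train and evaluate."""
    cfg = config or MLExperimentConfig()
    X, y = smote_oversample(
        features, labels,
        target_minority_count=cfg.target_minority_count,
        k_neighbors=cfg.oversample_k_neighbors, seed=cfg.seed,
    )
    train_idx, test_idx = split_train_test(X, y, cfg)
    return train_evaluate(X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                          validations, cfg, model_zoo)
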