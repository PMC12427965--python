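"""Phase I — diversity-aware base-learner pool with BA-optimised tuning.

Six classifiers from distinct learning paradigms (bagging and boosting
tree ensembles, two SVM kernels, an instance-based learner and a
probabilistic learner) are each tuned by an exhaustive grid search over
a shared stratified k-fold partition, optimising mean validation
balanced accuracy. All seven metrics are recorded per fold on both the
training folds and the validation fold so that Phase II can compute
generalization stability gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import METRIC_NAMES, aggregate_cv, all_metrics

__all__ = [
    "POOL_LEARNERS", "DEFAULT_GRIDS", "DEFAULT_META_GRID",
    "FoldScores", "TunedModel",
    "make_cv_folds", "make_learner", "run_grid_search",
    "fit_pool", "collect_pool_report",
]

log = logging.getLogger(__name__)

POOL_LEARNERS = ("RF", "XGBoost", "SVM_RBF", "SVM_Poly", "KNN", "GNB")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [None, 5, 10]},
    "XGBoost": {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1, 0.3],
                "max_depth": [3, 5]},
    "SVM_RBF": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "SVM_Poly": {"C": [0.1, 1.0, 10.0], "degree": [2, 3]},
    "KNN": {"n_neighbors": [3, 5, 7, 11], "weights": ["uniform", "distance"]},
    "GNB": {"var_smoothing": [1e-9, 1e-8]},
}

DEFAULT_META_GRID: dict[str, list] = {
    "hidden_layer_sizes": [(16,), (32,), (32, 16)],
    "alpha": [1e-4, 1e-3],
}

#: single-configuration grids for fast, desk-scale runs
COMPACT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100], "max_depth": [None]},
    "XGBoost": {"n_estimators": [100], "learning_rate": [0.1], "max_depth": [3]},
    "SVM_RBF": {"C": [1.0], "gamma": ["scale"]},
    "SVM_Poly": {"C": [1.0], "degree": [3]},
    "KNN": {"n_neighbors": [5], "weights": ["uniform"]},
    "GNB": {"var_smoothing": [1e-9]},
}

COMPACT_META_GRID: dict[str, list] = {
    "hidden_layer_sizes": [(16,)], "alpha": [1e-3],
}


def make_learner(name: str, random_state: int | None = None, **params):
    """Instantiate a pool learner (or the MLP meta-learner) by name.

    SVMs are wrapped in Platt-style sigmoid calibration of their
    decision values so class probabilities are available for
    Brier/JSD/stacking.
    """
    if name == "RF":
        return RandomForestClassifier(random_state=random_state, **params)
    if name == "XGBoost":
        return XGBClassifier(random_state=random_state, eval_metric="logloss",
                             n_jobs=1, **params)
    if name in ("SVM_RBF", "SVM_Poly"):
        kernel = "rbf" if name == "SVM_RBF" else "poly"
        base = SVC(kernel=kernel, random_state=random_state, **params)
        return CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "GNB":
        return GaussianNB(**params)
    if name == "MLP":
        return MLPClassifier(random_state=random_state, max_iter=2000,
                             learning_rate="adaptive", **params)
    raise ValueError(f"unknown learner {name!r}")


def make_cv_folds(y, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment, shared by every learner and phase.

    Returns an integer array of fold ids (0..k-1), one per sample.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for i, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[val_idx] = i
    return folds


@dataclass
class FoldScores:
    """Per-fold metric values on the training folds and validation fold."""

    model: str
    train: list[dict[str, float]] = field(default_factory=list)
    val: list[dict[str, float]] = field(default_factory=list)
    fold_ids: list[int] = field(default_factory=list)


@dataclass
class TunedModel:
    """Grid-search winner for one learner family."""

    name: str
    params: dict
    estimator: object  # fitted on the full training set
    fold_scores: FoldScores
    #: (params, mean validation BA) for every evaluated configuration
    grid_history: list[tuple[dict, float]] = field(default_factory=list)


def _as_array(X):
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def _score_fold(est, X, y, idx) -> dict[str, float]:
    probs = est.predict_proba(X[idx])[:, 1]
    preds = (probs >= 0.5).astype(int)
    return all_metrics(y[idx], preds, probs)


def run_grid_search(
    name: str,
    grid: dict[str, list],
    X, y,
    folds: np.ndarray,
    random_state: int | None = 0,
) -> TunedModel:
    """Exhaustive BA-optimised grid search over a shared fold partition.

    For every configuration, trains on k-1 folds and scores all seven
    metrics on both the (in-sample) training folds and the held-out
    validation fold. Selects the configuration with the highest mean
    validation BA; ties keep the first configuration in deterministic
    grid enumeration order. The winner is refit on the full training
    set. A configuration that fails on any fold is excluded and logged.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    k = int(folds.max()) + 1

    best: tuple[float, dict, FoldScores] | None = None
    history: list[tuple[dict, float]] = []
    for params in ParameterGrid(grid):
        fs = FoldScores(model=name)
        try:
            for f in range(k):
                tr, va = folds != f, folds == f
                est = make_learner(name, random_state=random_state, **params)
                est.fit(X[tr], y[tr])
                fs.train.append(_score_fold(est, X, y, tr))
                fs.val.append(_score_fold(est, X, y, va))
                fs.fold_ids.append(f)
        except Exception as exc:  # noqa: BLE001 - learner failures are data-dependent
            log.warning("%s: configuration %s failed (%s); excluded", name, params, exc)
            continue
        mean_val_ba = float(np.mean([m["balanced_accuracy"] for m in fs.val]))
        history.append((dict(params), mean_val_ba))
        if best is None or mean_val_ba > best[0]:
            best = (mean_val_ba, dict(params), fs)
    if best is None:
        raise RuntimeError(f"{name}: every grid configuration failed")

    final = make_learner(name, random_state=random_state, **best[1])
    final.fit(X, y)
    return TunedModel(name=name, params=best[1], estimator=final,
                      fold_scores=best[2], grid_history=history)


def fit_pool(
    X, y,
    folds: np.ndarray,
    grids: dict[str, dict] | None = None,
    random_state: int | None = 0,
) -> list[TunedModel]:
    """Tune every learner of the six-member pool on the shared folds."""
    grids = dict(DEFAULT_GRIDS if grids is None else grids)
    return [run_grid_search(name, grids[name], X, y, folds, random_state)
            for name in POOL_LEARNERS if name in grids]


def collect_pool_report(tuned: list[TunedModel]) -> pd.DataFrame:
    """Cross-validation comparison table: one row per model.

    Columns are ``<metric>_mean`` / ``<metric>_sd`` over validation
    folds for all seven metrics.
    """
    if not tuned:
        raise ValueError("no tuned models")
    rows = []
    for tm in tuned:
        rep = aggregate_cv(tm.fold_scores.val)
        row = {"model": tm.name}
        for m in METRIC_NAMES:
            row[f"{m}_mean"] = rep.means[m]
            row[f"{m}_sd"] = rep.sds[m]
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
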