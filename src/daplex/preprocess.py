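"""Leakage-free splitting and feature transformation.

The cohort is split once, stratified by diagnosis, into a training set
and an untouched holdout test set. All transformation parameters
(z-score means/SDs, one-hot category lists) are learned from training
rows only and applied identically to both partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["SplitResult", "TransformSpec", "CohortTransformer",
           "stratified_split", "fit_transform_spec", "apply_transform"]


@dataclass(frozen=True)
class SplitResult:
    """A single fixed stratified train/holdout partition."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.concatenate([self.train_indices, self.test_indices]),
            "part": ["train"] * len(self.train_indices) + ["test"] * len(self.test_indices),
        })


def stratified_split(
    cohort: pd.DataFrame, fraction: float = 0.8, seed: int = 0,
    label_col: str = "diagnosis",
) -> SplitResult:
    """Stratified train/holdout split with largest-remainder allocation.

    Per-class training counts are ``floor(fraction * n_class)`` with the
    leftover seats (to reach ``round(fraction * n_total)``) given to the
    classes with the largest fractional remainders, so each partition's
    class proportions differ from exact stratification by at most one
    patient. For the 474/394 cohort at fraction 0.8 this yields 694
    training and 174 holdout patients.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = cohort[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")

    target_total = int(round(fraction * len(y)))
    exact = fraction * counts
    base = np.floor(exact).astype(int)
    remainders = exact - base
    extras = target_total - base.sum()
    order = np.argsort(-remainders, kind="stable")
    take = base.copy()
    for i in range(int(extras)):
        take[order[i % len(classes)]] += 1

    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls, n_train in zip(classes, take):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(len(idx))
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return SplitResult(train_indices=train, test_indices=test,
                       fraction=fraction, seed=seed)


@dataclass
class TransformSpec:
    """Fitted transformation parameters (training data only).

    ``continuous`` maps feature name to (mean, sd, zero_variance_flag);
    a zero-variance feature keeps scale 1 so the column layout stays
    stable. ``categorical`` maps feature name to its ordered training
    category list (full indicator set, no reference level dropped;
    unseen test categories map to all-zero indicators).
    ``feature_group_map`` maps every emitted column to its source
    clinical variable.
    """

    continuous: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    categorical: dict[str, list] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)
    feature_group_map: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "continuous": {k: list(v) for k, v in self.continuous.items()},
            "categorical": {k: [str(c) for c in v] for k, v in self.categorical.items()},
            "columns": self.columns,
            "feature_group_map": self.feature_group_map,
        }, indent=2)

    @property
    def groups(self) -> dict[str, list[str]]:
        """Source variable -> list of emitted columns."""
        out: dict[str, list[str]] = {}
        for col, src in self.feature_group_map.items():
            out.setdefault(src, []).append(col)
        return out


def _infer_types(table: pd.DataFrame, continuous=None, categorical=None):
    continuous = list(continuous) if continuous is not None else None
    categorical = list(categorical) if categorical is not None else None
    if continuous is not None and categorical is not None:
        return continuous, categorical
    cont, cat = [], []
    for c in table.columns:
        if continuous is not None and c in continuous:
            cont.append(c)
        elif categorical is not None and c in categorical:
            cat.append(c)
        elif not pd.api.types.is_numeric_dtype(table[c]) or pd.api.types.is_bool_dtype(table[c]):
            cat.append(c)
        elif table[c].nunique() <= 2 and pd.api.types.is_integer_dtype(table[c]):
            cat.append(c)  # 0/1 indicator stored as ints
        else:
            cont.append(c)
    return cont, cat


def fit_transform_spec(
    train: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> TransformSpec:
    """Learn z-score and one-hot parameters from training rows only.

    Continuous features use the training mean and sample SD (ddof=1);
    a zero-SD feature is scaled by 1 and flagged. Categorical features
    record the sorted training category list; each level becomes one
    indicator column named ``<var>=<level>``.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    cont, cat = _infer_types(train, continuous, categorical)
    spec = TransformSpec()
    for name in train.columns:
        if name in cont:
            x = train[name].to_numpy(dtype=float)
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            flagged = sd == 0.0
            spec.continuous[name] = (mean, 1.0 if flagged else sd, flagged)
            spec.columns.append(name)
            spec.feature_group_map[name] = name
        elif name in cat:
            levels = sorted(train[name].unique(), key=str)
            spec.categorical[name] = list(levels)
            for lv in levels:
                col = f"{name}={lv}"
                spec.columns.append(col)
                spec.feature_group_map[col] = name
    return spec


def apply_transform(spec: TransformSpec, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted TransformSpec, preserving row order.

    Returns a float DataFrame with exactly the fitted column layout.
    Categories unseen during fitting map to all-zero indicators.
    """
    missing = [v for v in list(spec.continuous) + list(spec.categorical)
               if v not in table.columns]
    if missing:
        raise KeyError(f"table is missing source variables: {missing}")
    data = {}
    for name, (mean, sd, _flag) in spec.continuous.items():
        data[name] = (table[name].to_numpy(dtype=float) - mean) / sd
    for name, levels in spec.categorical.items():
        col = table[name].to_numpy()
        for lv in levels:
            data[f"{name}={lv}"] = (col == lv).astype(float)
    out = pd.DataFrame(data, index=table.index)
    return out[spec.columns]


class CohortTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :class:`TransformSpec`.

    Parameters
    ----------
    continuous, categorical : optional lists of column names. Columns
        not listed are typed by dtype (non-numeric or 0/1 integer
        columns are treated as categorical).
    """

    def __init__(self, continuous=None, categorical=None):
        self.continuous = continuous
        self.categorical = categorical

    def fit(self, X: pd.DataFrame, y=None):
        self.spec_ = fit_transform_spec(X, self.continuous, self.categorical)
        self.columns_ = list(self.spec_.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return apply_transform(self.spec_, X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.columns_, dtype=object)
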