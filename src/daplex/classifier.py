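"""DaplexClassifier — the three-phase knowledge-fusion ensemble.

A scikit-learn style estimator for binary diagnostic classification on
tabular clinical data. ``fit`` runs the full pipeline on a raw
predictor DataFrame:

* Phase I: leakage-free preprocessing (one-hot + z-score learned on
  the training data), a shared stratified k-fold partition and
  BA-optimised grid-search tuning of a six-learner heterogeneous pool;
* Phase II: stability-gap pruning (Δ_BA > threshold excludes a
  learner);
* Phase III: complementarity analysis (Friedman test, pairwise JSD),
  out-of-fold probabilities, Borda-consensus permutation importance,
  and an MLP meta-learner trained on the standardized hybrid
  meta-input.

``predict_proba`` routes new patients through the stored transform,
the full-training-refit base learners and the meta-learner.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import fusion, pool, pruning
from .preprocess import CohortTransformer

__all__ = ["DaplexClassifier"]


class DaplexClassifier(ClassifierMixin, BaseEstimator):
    """Diversity-aware pruned stacking ensemble with hybrid meta-input.

    Parameters
    ----------
    grids : mapping learner name -> hyperparameter grid, or None for
        the documented defaults (``pool.DEFAULT_GRIDS``).
    meta_grid : hyperparameter grid for the MLP meta-learner.
    cv : number of stratified folds shared by all phases.
    prune_threshold : stability-gap exclusion threshold on the anchor
        metric (strict inequality).
    anchor_metric : metric anchoring the pruning decision.
    n_consensus_features : k, number of Borda-consensus variables fused
        into the meta-input.
    n_permutation_repeats : repeats per variable for permutation
        importance.
    continuous, categorical : optional explicit column typing for the
        preprocessing step; unlisted columns are typed by dtype.
    random_state : single seed driving folds and every learner.

    Attributes (after ``fit``)
    --------------------------
    classes_, transformer_, fold_ids_, pool_, pool_report_,
    stability_report_, retained_, oof_, complementarity_,
    importance_rankings_, consensus_, meta_input_, meta_,
    meta_report_, meta_gaps_
    """

    def __init__(
        self,
        grids: dict | None = None,
        meta_grid: dict | None = None,
        cv: int = 5,
        prune_threshold: float = 0.05,
        anchor_metric: str = "balanced_accuracy",
        n_consensus_features: int = 5,
        n_permutation_repeats: int = 10,
        continuous: list[str] | None = None,
        categorical: list[str] | None = None,
        random_state: int | None = 0,
    ):
        self.grids = grids
        self.meta_grid = meta_grid
        self.cv = cv
        self.prune_threshold = prune_threshold
        self.anchor_metric = anchor_metric
        self.n_consensus_features = n_consensus_features
        self.n_permutation_repeats = n_permutation_repeats
        self.continuous = continuous
        self.categorical = categorical
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "DaplexClassifier":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of predictor columns")
        y = np.asarray(y).astype(int)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification requires exactly two classes")
        seed = 0 if self.random_state is None else int(self.random_state)

        # preprocessing, fitted on the training table only
        self.transformer_ = CohortTransformer(self.continuous, self.categorical).fit(X)
        Xt = self.transformer_.transform(X)

        # Phase I
        self.fold_ids_ = pool.make_cv_folds(y, k=self.cv, seed=seed)
        self.pool_ = pool.fit_pool(Xt, y, self.fold_ids_, grids=self.grids,
                                   random_state=seed)
        self.pool_report_ = pool.collect_pool_report(self.pool_)

        # Phase II
        gaps = {tm.name: pruning.stability_gaps(tm.fold_scores) for tm in self.pool_}
        self.stability_report_ = pruning.prune(
            gaps, threshold=self.prune_threshold, anchor=self.anchor_metric)
        self.retained_ = [tm for tm in self.pool_
                          if tm.name in self.stability_report_.retained]

        # Phase III: complementarity
        ba_matrix = np.column_stack([
            [d["balanced_accuracy"] for d in tm.fold_scores.val]
            for tm in self.retained_
        ])
        oof, fold_models = fusion.oof_probabilities(
            self.retained_, Xt, y, self.fold_ids_, random_state=seed,
            return_fold_models=True)
        self.oof_ = oof
        stat, df, p = fusion.friedman_test(ba_matrix)
        self.complementarity_ = fusion.ComplementarityReport(
            friedman_statistic=stat, degrees_of_freedom=df, p_value=p,
            jsd=fusion.jsd_matrix(oof))

        # Phase III: consensus importance
        group_map = self.transformer_.spec_.feature_group_map
        self.importance_rankings_ = [
            fusion.cross_validated_importance(
                tm, fold_models[tm.name], Xt, y, self.fold_ids_, group_map,
                n_repeats=self.n_permutation_repeats, seed=seed)
            for tm in self.retained_
        ]
        self.consensus_ = fusion.borda_aggregate(
            self.importance_rankings_, k=self.n_consensus_features)

        # Phase III: hybrid meta-input and meta-learner
        groups = self.transformer_.spec_.groups
        self.meta_input_ = fusion.build_meta_input(
            oof, Xt, self.consensus_, groups, y)
        self.meta_ = fusion.train_meta_learner(
            self.meta_input_, y, self.fold_ids_, grid=self.meta_grid,
            random_state=seed)
        from .metrics import aggregate_cv
        self.meta_report_ = aggregate_cv(self.meta_.fold_scores.val)
        self.meta_gaps_ = pruning.stability_gaps(self.meta_.fold_scores)
        return self

    # ------------------------------------------------------------------
    def _meta_features(self, X: pd.DataFrame) -> np.ndarray:
        Xt = self.transformer_.transform(X)
        Xa = Xt.to_numpy(dtype=float)
        probs = np.column_stack([
            tm.estimator.predict_proba(Xa)[:, 1] for tm in self.retained_
        ])
        feats = Xt[self.meta_input_.feature_columns].to_numpy(dtype=float)
        raw = np.column_stack([probs, feats])
        return (raw - self.meta_input_.means) / self.meta_input_.sds

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "meta_")
        return self.meta_.estimator.predict_proba(self._meta_features(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Diagnosis labels; pneumonia probability thresholded at 0.5."""
        p = self.predict_proba(X)[:, 1]
        return (p >= 0.5).astype(int)

    def base_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        """Holdout positive-class probabilities of every pool learner."""
        check_is_fitted(self, "pool_")
        Xa = self.transformer_.transform(X).to_numpy(dtype=float)
        return pd.DataFrame(
            {tm.name: tm.estimator.predict_proba(Xa)[:, 1] for tm in self.pool_},
            index=X.index)
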