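"""Phase III — complementarity analysis and knowledge fusion.

The retained learners are first checked for complementarity: a
Friedman rank test over their cross-validation BA scores (do the
models behave distinctly?) and pairwise Jensen–Shannon divergence
between their per-patient predictive distributions (do they reason
differently about individual patients?).

Fusion then builds a hybrid meta-input for the MLP meta-learner from
two streams: (i) each retained learner's out-of-fold predicted
probability of pneumonia, and (ii) the values of the top-k consensus
features obtained by Borda (rank-sum) aggregation of grouped
permutation-importance rankings across the retained learners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .metrics import confusion_counts, threshold_metrics
from .pool import TunedModel, make_learner, run_grid_search, _as_array

__all__ = [
    "ComplementarityReport", "ImportanceRanking", "BordaConsensus", "MetaInput",
    "friedman_test", "jsd", "jsd_matrix", "oof_probabilities",
    "grouped_permutation_importance", "borda_aggregate",
    "consensus_columns", "build_meta_input", "train_meta_learner",
]


# --------------------------------------------------------------------
# complementarity
# --------------------------------------------------------------------

def friedman_test(score_matrix) -> tuple[float, int, float]:
    """Friedman rank test across matched blocks (CV folds) and models.

    ``score_matrix`` has shape (folds, models). Ranks are assigned
    within each fold with midrank ties; the tie-corrected chi-square
    statistic is

        chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2
               / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    with df = models - 1. An all-tied matrix yields (0, df, 1).
    """
    M = np.asarray(score_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("score matrix must be at least 2 folds x 2 models")
    n, k = M.shape
    ranks = np.apply_along_axis(rankdata, 1, M)
    col_sums = ranks.sum(axis=0)
    denom = (ranks ** 2).sum() - n * k * (k + 1) ** 2 / 4.0
    df = k - 1
    if denom <= 0:  # every fold fully tied
        return 0.0, df, 1.0
    statistic = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum() / denom
    p = float(stats.chi2.sf(statistic, df))
    return float(statistic), df, p


def _xlog2x(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def jsd(p, q) -> float:
    """Base-2 Jensen–Shannon divergence between two discrete distributions.

    JSD = 0.5*KL(p||m) + 0.5*KL(q||m) with m = (p+q)/2; lies in [0, 1]
    with 0*log 0 taken as 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a probability distribution")
    m = (p + q) / 2.0
    # H(m) - (H(p)+H(q))/2 expressed through x*log2(x)
    val = float(_xlog2x(p).sum() / 2 + _xlog2x(q).sum() / 2 - _xlog2x(m).sum())
    return min(max(val, 0.0), 1.0)


def _pairwise_mean_jsd(pa: np.ndarray, pb: np.ndarray) -> float:
    # vectorised mean per-patient JSD of the binary distributions
    # (p, 1-p) vs (q, 1-q), base 2
    P = np.column_stack([pa, 1.0 - pa])
    Q = np.column_stack([pb, 1.0 - pb])
    M = (P + Q) / 2.0
    vals = (_xlog2x(P).sum(axis=1) + _xlog2x(Q).sum(axis=1)) / 2.0 - _xlog2x(M).sum(axis=1)
    return float(np.clip(vals, 0.0, 1.0).mean())


def jsd_matrix(prob_outputs: pd.DataFrame) -> pd.DataFrame:
    """Pairwise model divergence averaged over patients.

    ``prob_outputs`` is a patients × models frame of positive-class
    probabilities. Entry (a, b) is the mean over patients of the JSD
    between the two models' per-patient binary outcome distributions.
    """
    if prob_outputs.isna().any().any():
        raise ValueError("probability outputs contain undefined entries")
    models = list(prob_outputs.columns)
    out = pd.DataFrame(0.0, index=models, columns=models)
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            v = _pairwise_mean_jsd(prob_outputs[a].to_numpy(),
                                   prob_outputs[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = v
    return out


@dataclass(frozen=True)
class ComplementarityReport:
    friedman_statistic: float
    degrees_of_freedom: int
    p_value: float
    jsd: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "friedman_statistic": self.friedman_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "jsd": self.jsd.to_dict(),
        }


# --------------------------------------------------------------------
# out-of-fold probabilities
# --------------------------------------------------------------------

def oof_probabilities(
    retained: list[TunedModel], X, y, folds: np.ndarray,
    random_state: int | None = 0,
    return_fold_models: bool = False,
):
    """Out-of-fold positive-class probabilities for each retained learner.

    Each patient's probability comes from a clone (with the learner's
    selected hyperparameters) trained on the other folds of the same
    partition used in Phase I, so no model ever scores a patient it was
    trained on. Optionally also returns the per-fold fitted models for
    reuse (e.g. fold-wise permutation importance).
    """
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    if len(folds) != len(y):
        raise ValueError("fold assignment does not match the data")
    k = int(folds.max()) + 1
    oof = pd.DataFrame(np.nan, index=np.arange(len(y)),
                       columns=[tm.name for tm in retained])
    fold_models: dict[str, list] = {tm.name: [None] * k for tm in retained}
    for tm in retained:
        for f in range(k):
            tr, va = folds != f, folds == f
            est = make_learner(tm.name, random_state=random_state, **tm.params)
            est.fit(X[tr], y[tr])
            oof.loc[va, tm.name] = est.predict_proba(X[va])[:, 1]
            fold_models[tm.name][f] = est
    if oof.isna().any().any():
        raise RuntimeError("out-of-fold coverage incomplete")
    if return_fold_models:
        return oof, fold_models
    return oof


# --------------------------------------------------------------------
# consensus feature importance
# --------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceRanking:
    """Grouped permutation importance of one model over source variables."""

    model: str
    importance: dict[str, float]  # mean BA drop per source variable
    ranks: dict[str, int]  # 1 = most important


def _rank_importances(model: str, importance: dict[str, float]) -> ImportanceRanking:
    ordered = sorted(importance, key=lambda v: (-importance[v], v))
    return ImportanceRanking(model=model, importance=dict(importance),
                             ranks={v: i + 1 for i, v in enumerate(ordered)})


def _ba(y_true, y_pred) -> float:
    return threshold_metrics(confusion_counts(y_true, y_pred))["balanced_accuracy"]


def grouped_permutation_importance(
    model, X_val: pd.DataFrame, y_val,
    group_map: dict[str, str],
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceRanking:
    """Permutation importance by source clinical variable.

    All emitted columns of a source variable (e.g. every one-hot
    indicator) are permuted jointly with the same row permutation;
    importance is the mean drop in validation BA over ``n_repeats``.
    Ranks are assigned by descending importance, ties broken by
    variable name.
    """
    if len(X_val) == 0:
        raise ValueError("empty validation set")
    missing = [c for c in X_val.columns if c not in group_map]
    if missing:
        raise ValueError(f"group_map does not cover columns: {missing}")
    y_val = np.asarray(y_val).astype(int)
    rng = np.random.default_rng(seed)
    base = _ba(y_val, model.predict(X_val.to_numpy(dtype=float)))

    groups: dict[str, list[int]] = {}
    for j, col in enumerate(X_val.columns):
        groups.setdefault(group_map[col], []).append(j)

    Xv = X_val.to_numpy(dtype=float)
    importance = {}
    name = getattr(model, "daplex_name", type(model).__name__)
    for var, cols in groups.items():
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(Xv))
            Xp = Xv.copy()
            Xp[:, cols] = Xv[np.ix_(perm, cols)]
            drops.append(base - _ba(y_val, model.predict(Xp)))
        importance[var] = float(np.mean(drops))
    return _rank_importances(name, importance)


def cross_validated_importance(
    tm: TunedModel, fold_models: list, X: pd.DataFrame, y, folds: np.ndarray,
    group_map: dict[str, str], n_repeats: int = 10, seed: int = 0,
) -> ImportanceRanking:
    """Fold-averaged grouped permutation importance for one learner.

    Each fold model is scored on its own held-out validation fold (the
    rows it never saw); per-variable importances are averaged across
    folds before ranking.
    """
    y = np.asarray(y).astype(int)
    sums: dict[str, float] = {}
    for f, est in enumerate(fold_models):
        va = folds == f
        r = grouped_permutation_importance(
            est, X.loc[va], y[va], group_map, n_repeats=n_repeats,
            seed=seed + f)
        for var, imp in r.importance.items():
            sums[var] = sums.get(var, 0.0) + imp
    mean_imp = {v: s / len(fold_models) for v, s in sums.items()}
    return _rank_importances(tm.name, mean_imp)


@dataclass(frozen=True)
class BordaConsensus:
    """Rank-sum consensus feature importance across learners."""

    table: pd.DataFrame  # columns: borda_score, mean_importance, consensus_rank
    top_k: list[str]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def borda_aggregate(rankings: list[ImportanceRanking], k: int = 5) -> BordaConsensus:
    """Aggregate per-model rankings by the rank-sum Borda variant.

    A variable's Borda score is the sum of its ranks across models
    (lower = more consensus importance). Ties are broken by mean raw
    importance (descending), then by variable name.
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    variables = set(rankings[0].ranks)
    for r in rankings[1:]:
        if set(r.ranks) != variables:
            raise ValueError("rankings cover inconsistent variable sets")
    if k > len(variables):
        raise ValueError("k exceeds the number of variables")
    scores = {v: sum(r.ranks[v] for r in rankings) for v in variables}
    mean_imp = {v: float(np.mean([r.importance[v] for r in rankings]))
                for v in variables}
    order = sorted(variables, key=lambda v: (scores[v], -mean_imp[v], v))
    table = pd.DataFrame({
        "borda_score": [scores[v] for v in order],
        "mean_importance": [mean_imp[v] for v in order],
        "consensus_rank": np.arange(1, len(order) + 1),
    }, index=pd.Index(order, name="variable"))
    return BordaConsensus(table=table, top_k=order[:k])


# --------------------------------------------------------------------
# hybrid meta-input and meta-learner
# --------------------------------------------------------------------

def consensus_columns(
    top_k: list[str], groups: dict[str, list[str]],
    X_train: pd.DataFrame, y_train,
) -> dict[str, str]:
    """Pick one emitted feature column to represent each consensus variable.

    A continuous variable is its own column. A one-hot encoded variable
    contributes the indicator most correlated (|Pearson|, on training
    data) with the diagnosis label; ties break by column name.
    """
    y = np.asarray(y_train, dtype=float)
    rep = {}
    for var in top_k:
        cols = groups.get(var)
        if not cols:
            raise KeyError(f"consensus variable {var!r} absent from the feature matrix")
        if len(cols) == 1:
            rep[var] = cols[0]
            continue
        best, best_abs = None, -1.0
        for c in sorted(cols):
            x = X_train[c].to_numpy(dtype=float)
            sx = x.std()
            r = 0.0 if sx == 0 or y.std() == 0 else abs(float(np.corrcoef(x, y)[0, 1]))
            if r > best_abs + 1e-12:
                best, best_abs = c, r
        rep[var] = best
    return rep


@dataclass
class MetaInput:
    """Standardized hybrid meta-feature matrix.

    Columns are, in order, the retained learners' positive-class
    probabilities followed by one representative column per consensus
    variable; all columns z-scored with stored parameters.
    """

    X: pd.DataFrame
    prob_columns: list[str]
    feature_columns: list[str]
    means: np.ndarray
    sds: np.ndarray

    @property
    def columns(self) -> list[str]:
        return self.prob_columns + self.feature_columns


def _standardize_fit(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    return means, sds


def build_meta_input(
    oof: pd.DataFrame, X_train: pd.DataFrame,
    consensus: BordaConsensus, groups: dict[str, list[str]], y_train,
    representatives: dict[str, str] | None = None,
) -> MetaInput:
    """Assemble and z-score the hybrid meta-input.

    Column count = number of retained learners + k consensus variables.
    """
    if len(oof) != len(X_train):
        raise ValueError("out-of-fold matrix and training features are misaligned")
    if representatives is None:
        representatives = consensus_columns(consensus.top_k, groups, X_train, y_train)
    feat_cols = [representatives[v] for v in consensus.top_k]
    raw = np.column_stack([
        oof.to_numpy(dtype=float),
        X_train[feat_cols].to_numpy(dtype=float),
    ])
    means, sds = _standardize_fit(raw)
    Z = (raw - means) / sds
    names = [f"prob_{m}" for m in oof.columns] + [f"feat_{v}" for v in consensus.top_k]
    return MetaInput(
        X=pd.DataFrame(Z, columns=names, index=X_train.index),
        prob_columns=list(oof.columns),
        feature_columns=feat_cols,
        means=means, sds=sds,
    )


def train_meta_learner(
    meta: MetaInput, y, folds: np.ndarray,
    grid: dict[str, list] | None = None,
    random_state: int | None = 0,
) -> TunedModel:
    """Tune the MLP meta-learner with the shared grid-search machinery.

    Uses the same stratified folds and BA-optimised exhaustive search
    as Phase I, so the meta-learner's own stability gap is reportable.
    """
    from .pool import DEFAULT_META_GRID  # local import keeps defaults in one place
    grid = DEFAULT_META_GRID if grid is None else grid
    return run_grid_search("MLP", grid, meta.X, y, folds, random_state=random_state)
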