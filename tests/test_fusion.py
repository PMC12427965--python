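"""Phase III: complementarity measures, consensus importance, meta-learning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from daplex.fusion import (ImportanceRanking, borda_aggregate, build_meta_input,
                           consensus_columns, friedman_test,
                           grouped_permutation_importance, jsd, jsd_matrix,
                           oof_probabilities, train_meta_learner)
from daplex.pool import make_cv_folds, run_grid_search


def _friedman_oracle(M):
    """Direct Friedman computation: midranks per block, tie-corrected."""
    M = np.asarray(M, float)
    n, k = M.shape
    ranks = np.array([stats.rankdata(row) for row in M])
    col_sums = ranks.sum(axis=0)
    denom = (ranks ** 2).sum() - n * k * (k + 1) ** 2 / 4
    if denom == 0:
        return 0.0
    return (k - 1) * ((col_sums - n * (k + 1) / 2) ** 2).sum() / denom


class TestFriedman:
    def test_identical_columns_degenerate(self):
        stat, df, p = friedman_test(np.ones((5, 4)))
        assert stat == 0.0 and p == 1.0 and df == 3

    def test_degrees_of_freedom_is_models_minus_one(self, rng):
        stat, df, p = friedman_test(rng.uniform(size=(5, 5)))
        assert df == 4

    @pytest.mark.parametrize("shape", [(4, 3), (5, 5), (3, 2), (5, 4)])
    def test_matches_rank_formula_oracle(self, shape, rng):
        M = rng.uniform(size=shape)
        M[0, :2] = 0.5  # inject a tie
        stat, _, _ = friedman_test(M)
        assert stat == pytest.approx(_friedman_oracle(M), abs=1e-10)

    def test_matches_scipy_without_ties(self, rng):
        M = rng.normal(size=(6, 4))
        stat, _, p = friedman_test(M)
        ref = stats.friedmanchisquare(*[M[:, j] for j in range(4)])
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))


class TestJsd:
    def test_identical_distributions_zero(self):
        assert jsd([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_support_is_one(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_matches_two_term_kl_oracle(self):
        p, q = np.array([0.8, 0.2]), np.array([0.2, 0.8])
        m = (p + q) / 2
        kl = lambda a: sum(ai * math.log2(ai / mi) for ai, mi in zip(a, m))
        assert jsd(p, q) == pytest.approx((kl(p) + kl(q)) / 2, abs=1e-12)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            v = jsd(p, q)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(jsd(q, p), abs=1e-12)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            jsd([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError):
            jsd([-0.1, 1.1], [0.5, 0.5])


class TestJsdMatrix:
    def test_identical_models_zero_entry(self):
        probs = pd.DataFrame({"a": [0.1, 0.9, 0.4], "b": [0.1, 0.9, 0.4],
                              "c": [0.9, 0.1, 0.6]})
        M = jsd_matrix(probs)
        assert M.loc["a", "b"] == 0.0
        assert M.loc["a", "c"] > 0.0

    def test_antipodal_extreme_probabilities_near_one(self):
        pa = np.array([1e-9, 1 - 1e-9] * 5)
        M = jsd_matrix(pd.DataFrame({"a": pa, "b": 1 - pa}))
        assert M.loc["a", "b"] == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_zero_diagonal_unit_range(self, rng):
        probs = pd.DataFrame(rng.uniform(size=(30, 4)),
                             columns=list("abcd"))
        M = jsd_matrix(probs)
        assert np.allclose(M.to_numpy(), M.to_numpy().T, atol=1e-12)
        assert np.allclose(np.diag(M.to_numpy()), 0.0)
        assert ((M.to_numpy() >= 0) & (M.to_numpy() <= 1)).all()

    def test_matches_per_patient_oracle(self):
        probs = pd.DataFrame({"m1": [0.9, 0.2, 0.5, 0.7],
                              "m2": [0.1, 0.3, 0.5, 0.95],
                              "m3": [0.45, 0.55, 0.05, 0.6]})
        M = jsd_matrix(probs)
        for a in probs.columns:
            for b in probs.columns:
                oracle = np.mean([jsd([pa, 1 - pa], [pb, 1 - pb])
                                  for pa, pb in zip(probs[a], probs[b])])
                assert M.loc[a, b] == pytest.approx(oracle, abs=1e-10)

    def test_undefined_entries_rejected(self):
        with pytest.raises(ValueError):
            jsd_matrix(pd.DataFrame({"a": [0.1, np.nan], "b": [0.2, 0.3]}))


@pytest.fixture(scope="module")
def small_tuned():
    """Two cheap tuned models on a small separable problem."""
    rng = np.random.default_rng(3)
    n = 150
    X = np.r_[rng.normal(-2, 1, (n // 2, 4)), rng.normal(2, 1, (n // 2, 4))]
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    folds = make_cv_folds(y, 5, 0)
    tuned = [
        run_grid_search("GNB", {"var_smoothing": [1e-9]}, X, y, folds),
        run_grid_search("KNN", {"n_neighbors": [5], "weights": ["uniform"]},
                        X, y, folds),
    ]
    return X, y, folds, tuned


class TestOofProbabilities:
    def test_full_coverage_and_determinism(self, small_tuned):
        X, y, folds, tuned = small_tuned
        a = oof_probabilities(tuned, X, y, folds)
        b = oof_probabilities(tuned, X, y, folds)
        assert not a.isna().any().any()
        assert list(a.columns) == ["GNB", "KNN"]
        pd.testing.assert_frame_equal(a, b)

    def test_fold_mismatch_rejected(self, small_tuned):
        X, y, folds, tuned = small_tuned
        with pytest.raises(ValueError):
            oof_probabilities(tuned, X, y, folds[:-5])

    def test_memorizer_scores_chance_out_of_fold(self):
        """Leakage canary: 1-NN on pure-noise labels.

        In-sample the memorizer is perfect; out of fold it must drop to
        chance, proving no patient is scored by a model that saw it.
        """
        from daplex.metrics import confusion_counts, threshold_metrics
        rng = np.random.default_rng(7)
        n = 868
        X = rng.normal(size=(n, 8))
        y = rng.integers(0, 2, n)
        folds = make_cv_folds(y, 5, 0)
        tm = run_grid_search("KNN", {"n_neighbors": [1], "weights": ["uniform"]},
                             X, y, folds)
        # in-sample: memorized
        in_sample = tm.estimator.predict(X)
        ba_in = threshold_metrics(confusion_counts(y, in_sample))["balanced_accuracy"]
        assert ba_in == pytest.approx(1.0)
        # out of fold: chance
        oof = oof_probabilities([tm], X, y, folds)
        preds = (oof["KNN"].to_numpy() >= 0.5).astype(int)
        ba_oof = threshold_metrics(confusion_counts(y, preds))["balanced_accuracy"]
        assert abs(ba_oof - 0.5) < 0.05


class TestPermutationImportance:
    def test_label_copy_feature_ranks_first(self):
        """A feature equal to the label dominates: rank 1, importance ~ BA-0.5."""
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"label_copy": y.astype(float),
                          "noise1": rng.normal(size=n),
                          "noise2": rng.normal(size=n)})
        from daplex.pool import make_learner
        est = make_learner("RF", random_state=0, n_estimators=50).fit(X.to_numpy(), y)
        group_map = {c: c for c in X.columns}
        r = grouped_permutation_importance(est, X, y, group_map, n_repeats=5, seed=0)
        assert r.ranks["label_copy"] == 1
        assert r.importance["label_copy"] == pytest.approx(0.5, abs=0.1)
        for noise in ("noise1", "noise2"):
            assert abs(r.importance[noise]) < 0.05

    def test_grouped_columns_permuted_jointly(self):
        """One-hot siblings of a decisive variable share one importance."""
        rng = np.random.default_rng(1)
        n = 300
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"v=a": (y == 1).astype(float),
                          "v=b": (y == 0).astype(float),
                          "w": rng.normal(size=n)})
        from daplex.pool import make_learner
        est = make_learner("GNB").fit(X.to_numpy(), y)
        r = grouped_permutation_importance(
            est, X, y, {"v=a": "v", "v=b": "v", "w": "w"}, n_repeats=5, seed=0)
        assert set(r.importance) == {"v", "w"}
        assert r.ranks["v"] == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        from daplex.pool import make_learner
        est = make_learner("KNN", n_neighbors=5, weights="uniform").fit(
            X.to_numpy(), y)
        gm = {c: c for c in X.columns}
        r1 = grouped_permutation_importance(est, X, y, gm, n_repeats=4, seed=9)
        r2 = grouped_permutation_importance(est, X, y, gm, n_repeats=4, seed=9)
        assert r1.importance == r2.importance

    def test_empty_validation_rejected(self):
        from daplex.pool import make_learner
        est = make_learner("GNB").fit(np.zeros((4, 1)), [0, 1, 0, 1])
        with pytest.raises(ValueError):
            grouped_permutation_importance(
                est, pd.DataFrame({"x": []}), [], {"x": "x"})


def _ranking(model, ranks, importance=None):
    imp = importance or {v: 1.0 / r for v, r in ranks.items()}
    return ImportanceRanking(model=model, importance=imp, ranks=ranks)


class TestBordaAggregate:
    def test_unanimous_first_place(self):
        rankings = [_ranking(f"m{i}", {"v": 1, "w": 2, "x": 3}) for i in range(5)]
        c = borda_aggregate(rankings, k=2)
        assert c.table.loc["v", "borda_score"] == 5  # minimum possible = n models
        assert c.table.loc["v", "consensus_rank"] == 1
        assert c.top_k == ["v", "w"]

    def test_scores_non_decreasing_down_ranking(self, rng):
        variables = list("abcdefgh")
        rankings = []
        for i in range(5):
            perm = rng.permutation(variables)
            rankings.append(_ranking(f"m{i}", {v: j + 1 for j, v in enumerate(perm)}))
        c = borda_aggregate(rankings, k=5)
        scores = c.table["borda_score"].to_numpy()
        assert (np.diff(scores) >= 0).all()

    def test_matches_exhaustive_rank_sum_oracle(self):
        rankings = [
            _ranking("m1", {"a": 1, "b": 2, "c": 3, "d": 4}),
            _ranking("m2", {"a": 2, "b": 1, "c": 4, "d": 3}),
            _ranking("m3", {"a": 1, "b": 3, "c": 2, "d": 4}),
        ]
        c = borda_aggregate(rankings, k=4)
        oracle = {v: sum(r.ranks[v] for r in rankings) for v in "abcd"}
        for v in "abcd":
            assert c.table.loc[v, "borda_score"] == oracle[v]
        assert c.top_k[0] == "a" and c.top_k[-1] == "d"

    def test_tie_broken_by_mean_importance_then_name(self):
        rankings = [
            ImportanceRanking("m1", {"a": 0.1, "b": 0.3}, {"a": 1, "b": 2}),
            ImportanceRanking("m2", {"a": 0.1, "b": 0.3}, {"a": 2, "b": 1}),
        ]
        c = borda_aggregate(rankings, k=2)  # equal borda scores of 3
        assert c.top_k == ["b", "a"]  # b has higher mean importance

    def test_inconsistent_variable_sets_rejected(self):
        with pytest.raises(ValueError):
            borda_aggregate([_ranking("m1", {"a": 1, "b": 2}),
                             _ranking("m2", {"a": 1, "c": 2})], k=1)


class TestMetaInput:
    def _setup(self, rng, n=200):
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        X = pd.DataFrame({
            "crp": rng.normal(size=n) + y,
            "crackles=0": (1 - y).astype(float),
            "crackles=1": y.astype(float),
        })
        oof = pd.DataFrame({m: rng.uniform(size=n) for m in ["RF", "GNB"]})
        groups = {"crp": ["crp"], "crackles": ["crackles=0", "crackles=1"]}
        rankings = [_ranking("RF", {"crp": 1, "crackles": 2}),
                    _ranking("GNB", {"crackles": 1, "crp": 2})]
        consensus = borda_aggregate(rankings, k=2)
        return X, y, oof, groups, consensus

    def test_column_count_is_retained_plus_k(self, rng):
        X, y, oof, groups, consensus = self._setup(rng)
        meta = build_meta_input(oof, X, consensus, groups, y)
        assert meta.X.shape[1] == 2 + 2
        assert len(meta.X) == len(X)

    def test_columns_standardized(self, rng):
        X, y, oof, groups, consensus = self._setup(rng)
        meta = build_meta_input(oof, X, consensus, groups, y)
        assert np.allclose(meta.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(meta.X.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_categorical_representative_tracks_label(self, rng):
        X, y, oof, groups, consensus = self._setup(rng)
        rep = consensus_columns(["crackles"], groups, X, y)
        assert rep["crackles"] in ("crackles=0", "crackles=1")

    def test_missing_consensus_variable_raises(self, rng):
        X, y, oof, groups, consensus = self._setup(rng)
        with pytest.raises(KeyError):
            build_meta_input(oof, X, consensus, {"crp": ["crp"]}, y)

    def test_misaligned_rows_rejected(self, rng):
        X, y, oof, groups, consensus = self._setup(rng)
        with pytest.raises(ValueError):
            build_meta_input(oof.iloc[:-1], X, consensus, groups, y)


class TestMetaLearner:
    def test_separable_meta_input_perfect_ba(self, rng):
        """OOF columns equal to the label: validation BA ~ 1."""
        n = 200
        y = rng.integers(0, 2, n)
        y[:5] = [0, 1, 0, 1, 0]
        raw = pd.DataFrame({"prob_a": y.astype(float),
                            "prob_b": y.astype(float)})
        from daplex.fusion import MetaInput, _standardize_fit
        means, sds = _standardize_fit(raw.to_numpy(float))
        meta = MetaInput(X=(raw - means) / sds, prob_columns=["a", "b"],
                         feature_columns=[], means=means, sds=sds)
        folds = make_cv_folds(y, 5, 0)
        tm = train_meta_learner(meta, y, folds,
                                grid={"hidden_layer_sizes": [(8,)], "alpha": [1e-4]})
        val_ba = np.mean([d["balanced_accuracy"] for d in tm.fold_scores.val])
        assert val_ba > 0.99

    def test_fixed_seed_reproducible_selection(self, rng):
        n = 150
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        raw = rng.normal(size=(n, 3)) + y[:, None]
        from daplex.fusion import MetaInput, _standardize_fit
        means, sds = _standardize_fit(raw)
        meta = MetaInput(X=pd.DataFrame((raw - means) / sds),
                         prob_columns=list("abc"), feature_columns=[],
                         means=means, sds=sds)
        folds = make_cv_folds(y, 5, 0)
        grid = {"hidden_layer_sizes": [(4,), (8,)], "alpha": [1e-4]}
        a = train_meta_learner(meta, y, folds, grid=grid, random_state=5)
        b = train_meta_learner(meta, y, folds, grid=grid, random_state=5)
        assert a.params == b.params
        assert a.fold_scores.val == b.fold_scores.val
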