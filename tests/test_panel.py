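import numpy as np
import pandas as pd
import pytest

from mesotyper.containers import ExpressionMatrix
from mesotyper.panel import (FeatureVote, discretize, ensemble_vote,
                             feature_vote, model_importance, predict_subtype,
                             prune_correlated, rank_features, rfe_select,
                             stepwise_panel, train_final)


def _em(values, genes=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples))


def _binary_cohort(n_per=30, n_null=20, seed=0):
    """One perfectly class-tracking binary gene among null genes."""
    rng = np.random.default_rng(seed)
    y = pd.Series(["a"] * n_per + ["b"] * n_per,
                  index=[f"s{j}" for j in range(2 * n_per)])
    perfect = np.array([0.0] * n_per + [10.0] * n_per)
    nulls = rng.normal(5, 1, size=(n_null, 2 * n_per))
    X = _em(np.vstack([perfect, nulls]),
            genes=["perfect"] + [f"null{i}" for i in range(n_null)])
    return X, y


class TestFilterMethods:
    def test_perfect_predictor_maximal_under_all_three(self):
        X, y = _binary_cohort()
        for method in ("chi2", "info_gain", "fcbf"):
            res = rank_features(X, y, method)
            assert res.index[0] == "perfect"
        fcbf = rank_features(X, y, "fcbf")
        assert fcbf.loc["perfect", "score"] == pytest.approx(1.0)
        assert bool(fcbf.loc["perfect", "selected"])

    def test_constant_gene_scores_zero(self):
        y = pd.Series(["a", "a", "b", "b"],
                      index=[f"s{j}" for j in range(4)])
        X = _em(np.array([[3.0, 3.0, 3.0, 3.0],
                          [1.0, 2.0, 8.0, 9.0]]), genes=["flat", "good"])
        for method in ("chi2", "info_gain"):
            res = rank_features(X, y, method)
            assert res.loc["flat", "score"] == 0.0

    def test_chi2_matches_hand_computed_2x2(self):
        # table [[20,5],[5,20]]: chi2 = sum (O-E)^2/E with E=12.5 everywhere
        x = np.array([0] * 25 + [1] * 25)
        y_arr = np.array(["a"] * 20 + ["b"] * 5 + ["a"] * 5 + ["b"] * 20)
        y = pd.Series(y_arr, index=[f"s{j}" for j in range(50)])
        X = _em(x[None, :].astype(float), genes=["g"])
        res = rank_features(X, y, "chi2", n_bins=2)
        expected = 4 * (7.5 ** 2) / 12.5
        assert res.loc["g", "score"] == pytest.approx(expected, abs=1e-9)

    def test_fcbf_drops_duplicate_feature(self):
        X, y = _binary_cohort()
        dup = X.values.copy()
        dup.loc["copy"] = dup.loc["perfect"]
        res = rank_features(ExpressionMatrix(dup), y, "fcbf")
        assert bool(res.loc["perfect", "selected"]) != bool(
            res.loc["copy", "selected"]) or not bool(res.loc["copy",
                                                             "selected"])

    def test_discretize_equal_frequency(self):
        bins = discretize(np.arange(9, dtype=float), n_bins=3)
        assert list(np.bincount(bins)) == [3, 3, 3]


class TestModelMethods:
    def test_planted_gene_outranks_nulls(self):
        X, y = _binary_cohort(n_per=40, n_null=30, seed=1)
        for method in ("rf_mda", "gboost"):
            res = model_importance(X, y, method, seed=0)
            assert res.index[0] == "perfect"

    def test_boruta_confirms_informative_rejects_null(self):
        rng = np.random.default_rng(2)
        n = 120
        y = pd.Series(rng.choice(["a", "b"], n),
                      index=[f"s{j}" for j in range(n)])
        signal = np.vstack([(y == "a").to_numpy(dtype=float) * 2
                            + rng.normal(0, 0.3, n) for _ in range(5)])
        nulls = rng.normal(0, 1, size=(200, n))
        X = _em(np.vstack([signal, nulls]),
                genes=[f"info{i}" for i in range(5)]
                + [f"null{i}" for i in range(200)])
        res = model_importance(X, y, "boruta", seed=0)
        assert res.loc[[f"info{i}" for i in range(5)], "confirmed"].all()
        null_confirmed = res.loc[[f"null{i}" for i in range(200)],
                                 "confirmed"].sum()
        assert null_confirmed <= 10   # >= 95% rejected or tentative

    def test_rf_mda_constant_feature_near_zero(self):
        X, y = _binary_cohort(n_per=25, n_null=5, seed=3)
        flat = X.values.copy()
        flat.loc["flat"] = 4.2
        res = model_importance(ExpressionMatrix(flat), y, "rf_mda", seed=0)
        assert abs(res.loc["flat", "score"]) < 0.02


class TestVote:
    def test_thresholds_monotone(self):
        X, y = _binary_cohort(n_per=25, n_null=10, seed=4)
        votes = feature_vote(X, y, seed=0, n_top=5)
        p1 = set(ensemble_vote(votes, 1))
        p4 = set(ensemble_vote(votes, 4))
        p6 = set(ensemble_vote(votes, 6))
        assert p6 <= p4 <= p1

    def test_vote_counts_and_ordering(self):
        X, y = _binary_cohort(n_per=25, n_null=10, seed=5)
        votes = feature_vote(X, y, seed=0, n_top=5)
        assert votes.table.loc["perfect", "vote"] == 6
        assert ensemble_vote(votes, 6)[0] == "perfect"

    def test_empty_panel_warns(self):
        table = pd.DataFrame(
            {m: [False] for m in ("chi2", "info_gain", "fcbf", "rf_mda",
                                  "gboost", "boruta")}, index=["g"])
        table["vote"] = 0
        table["mean_rank"] = 1.0
        with pytest.warns(UserWarning, match="threshold"):
            assert ensemble_vote(FeatureVote(table), 4) == []


class TestPruneCorrelated:
    def test_hand_traced_three_feature_case(self):
        """r(f1,f2)=high, f3 independent; f1 has the larger mean absolute
        correlation, so f1 is dropped and {f2, f3} survive."""
        rng = np.random.default_rng(6)
        n = 200
        f2 = rng.normal(size=n)
        f3 = rng.normal(size=n)
        f1 = 0.97 * f2 + 0.2 * f3 + 0.1 * rng.normal(size=n)
        X = _em(np.vstack([f1, f2, f3]), genes=["f1", "f2", "f3"])
        corr = X.values.T.corr().abs()
        assert corr.loc["f1", "f2"] > 0.8
        mean_abs = (corr.sum(axis=1) - 1) / 2
        assert mean_abs["f1"] > mean_abs["f2"]
        out = prune_correlated(X, ["f1", "f2", "f3"], cutoff=0.8)
        assert out == ["f2", "f3"]

    def test_uncorrelated_panel_unchanged(self):
        rng = np.random.default_rng(7)
        X = _em(rng.normal(size=(5, 100)))
        assert prune_correlated(X, X.gene_ids, 0.8) == X.gene_ids

    def test_duplicated_feature_one_removed(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=50)
        X = _em(np.vstack([base, base, rng.normal(size=50)]),
                genes=["a", "b", "c"])
        out = prune_correlated(X, ["a", "b", "c"], 0.8)
        assert len(out) == 2 and "c" in out

    def test_output_never_exceeds_cutoff(self):
        rng = np.random.default_rng(9)
        latent = rng.normal(size=(3, 120))
        mix = rng.normal(size=(12, 3)) @ latent + 0.3 * rng.normal(
            size=(12, 120))
        X = _em(mix)
        out = prune_correlated(X, X.gene_ids, 0.8)
        corr = X.subset_genes(out).values.T.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.8


class TestPanelSizing:
    def _informative_cohort(self, n_info=5, n_null=40, n=150, seed=10):
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.choice(["a", "b", "c"], n),
                      index=[f"s{j}" for j in range(n)])
        rows = []
        for i in range(n_info):
            centers = dict(zip(["a", "b", "c"],
                               rng.permutation([0.0, 1.5, 3.0])))
            rows.append(y.map(centers).to_numpy()
                        + rng.normal(0, 0.7, n))
        rows.extend(rng.normal(0, 1, size=(n_null, n)))
        X = _em(np.vstack(rows), genes=[f"info{i}" for i in range(n_info)]
                + [f"null{i}" for i in range(n_null)])
        return X, y

    def test_stepwise_accuracy_plateaus_near_true_panel_size(self):
        X, y = self._informative_cohort()
        ranked = [f"info{i}" for i in range(5)] + [f"null{i}"
                                                   for i in range(10)]
        res = stepwise_panel(X, y, ranked, cv="kfold", seed=0, max_size=12)
        assert len(res.accuracy) == 12
        assert 3 <= res.chosen_size <= 7

    def test_rfe_recovers_planted_features_and_respects_min_size(self):
        X, y = self._informative_cohort(n_info=4, n_null=60, seed=11)
        coarse = y.map({"a": "x", "b": "y", "c": "y"})
        chosen, trace = rfe_select(X, coarse, cv="kfold", seed=0)
        assert set(f"info{i}" for i in range(4)) <= set(chosen)
        chosen_min, _ = rfe_select(X, coarse, cv="kfold", seed=0,
                                   min_size=10)
        assert len(chosen_min) >= 10
        assert trace["size"].is_monotonic_decreasing

    def test_rfe_needs_binary_labels(self):
        X, y = self._informative_cohort()
        with pytest.raises(ValueError, match="binary"):
            rfe_select(X, y)


class TestFinalModel:
    def _cohort(self, seed=12, n=200):
        rng = np.random.default_rng(seed)
        labels = np.array(["non_immune"] * (n // 2)
                          + ["immune_suppressed"] * (n // 4)
                          + ["immune_activated"] * (n - n // 2 - n // 4))
        rng.shuffle(labels)
        y = pd.Series(labels, index=[f"s{j}" for j in range(n)])
        rows, genes = [], []
        for i, cls in enumerate(["non_immune", "immune_suppressed",
                                 "immune_activated"]):
            for j in range(4):
                rows.append((y == cls).to_numpy(dtype=float) * 2.5
                            + rng.normal(0, 0.8, n))
                genes.append(f"cls{i}_{j}")
        for i in range(20):
            rows.append(rng.normal(0, 1, n))
            genes.append(f"null{i}")
        return _em(np.vstack(rows), genes=genes), y

    def test_split_stratified_within_one_sample(self):
        X, y = self._cohort()
        bundle = train_final(X, y, X.gene_ids[:12], seed=0,
                             families=("lda",))
        conf = bundle.confusion
        test_total = conf.to_numpy().sum()
        for cls, total in y.value_counts().items():
            in_test = conf.loc[f"true_{cls}"].sum()
            assert abs(in_test - 0.3 * total) <= 1.0

    def test_probabilities_row_sum_one_and_self_accuracy(self):
        X, y = self._cohort()
        bundle = train_final(X, y, X.gene_ids[:12], seed=0)
        labels, proba = predict_subtype(bundle, X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (labels.labels == y).mean() > 0.95
        assert labels.stage_tag == "predicted"

    def test_missing_panel_gene_error_names_gene(self):
        X, y = self._cohort()
        bundle = train_final(X, y, X.gene_ids[:8], seed=0,
                             families=("naive_bayes",))
        reduced = ExpressionMatrix(
            X.values.drop(index=bundle.panel[0]))
        with pytest.raises(KeyError, match=bundle.panel[0]):
            predict_subtype(bundle, reduced)

    def test_small_class_rejected(self):
        X, y = self._cohort()
        y2 = y.copy()
        y2.iloc[:] = "non_immune"
        y2.iloc[:3] = "immune_activated"
        with pytest.raises(ValueError, match=">= 5"):
            train_final(X, y2, X.gene_ids[:5], seed=0)

    def test_bundle_round_trip(self, tmp_path):
        X, y = self._cohort()
        bundle = train_final(X, y, X.gene_ids[:10], seed=0,
                             families=("lda", "naive_bayes"))
        bundle.save(tmp_path / "bundle")
        from mesotyper.panel import ClassifierBundle
        back = ClassifierBundle.load(tmp_path / "bundle")
        assert back.panel == bundle.panel
        assert back.family == bundle.family
        labels_a, proba_a = predict_subtype(bundle, X)
        labels_b, proba_b = predict_subtype(back, X)
        assert labels_a.labels.equals(labels_b.labels)


def test_rankings_invariant_to_gene_order():
    rng = np.random.default_rng(13)
    y = pd.Series(rng.choice(["a", "b"], 60),
                  index=[f"s{j}" for j in range(60)])
    X = _em(rng.normal(size=(15, 60)))
    perm = list(rng.permutation(X.gene_ids))
    Xp = X.subset_genes(perm)
    for method in ("chi2", "info_gain"):
        a = rank_features(X, y, method)["score"]
        b = rank_features(Xp, y, method)["score"]
        assert np.allclose(a.sort_index(), b.sort_index())
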