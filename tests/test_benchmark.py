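import numpy as np
import pandas as pd
import pytest

from t2asym.benchmark import (
    FILTERS,
    BenchmarkConfig,
    BSWiMSSelector,
    MethodSpec,
    RankFilterSelector,
    compute_metrics,
    rank_features,
    repeated_holdout,
    run_experiments,
    selection_frequency,
)


def planted_X(n=40, n_feat=12, effect=3.0, seed=0):
    """One strongly informative feature (column 0) among Gaussian noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["MCIs"] * (n // 2) + ["MCIp"] * (n - n // 2))
    X = rng.normal(size=(n, n_feat))
    X[y == "MCIp", 0] += effect
    cols = [f"f{i}" for i in range(n_feat)]
    return pd.DataFrame(X, columns=cols, index=[f"S{i}" for i in range(n)]), y


class TestFilters:
    @pytest.mark.parametrize("name", sorted(FILTERS))
    def test_every_filter_ranks_planted_feature_first(self, name):
        X, y = planted_X(effect=4.0, seed=3)
        order = rank_features(name, X, (y == "MCIp").astype(int), random_state=0)
        assert order[0] == 0, name

    def test_kendall_tau_of_class_labels_is_one(self):
        from scipy.stats import kendalltau

        y = np.array([0, 1] * 10)
        assert abs(kendalltau(y, y, variant="b").correlation) == pytest.approx(1.0)

    def test_mrmr_demotes_duplicated_informative_feature(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        strong = y + rng.normal(0, 0.3, n)
        weak = y + rng.normal(0, 1.2, n)
        X = np.column_stack([strong, strong.copy(), weak])
        order = list(rank_features("mrmr", X, y))
        # the duplicate (index 1) must fall below the independent weak feature
        assert order.index(1) > order.index(2)

    def test_constant_feature_ranked_last(self):
        X, y = planted_X(n_feat=6, seed=5)
        X["f5"] = 1.0
        for name in ("wilcoxon", "kendall", "idi", "nri"):
            order = list(rank_features(name, X, (y == "MCIp").astype(int)))
            assert order[-1] == 5, name

    def test_unknown_filter_rejected(self):
        with pytest.raises(KeyError):
            rank_features("nope", np.zeros((4, 2)), np.array([0, 0, 1, 1]))


class TestBSWiMS:
    def test_selects_informative_features(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 15))
        y = ((X[:, 2] + X[:, 9] + rng.normal(0, 0.7, 40)) > 0).astype(int)
        sel = BSWiMSSelector(random_state=1).fit(X, y)
        assert {2, 9} <= set(sel.selected_idx_)
        assert len(sel.selected_idx_) <= 6

    def test_transform_subsets_columns(self):
        X = np.random.default_rng(2).normal(size=(30, 8))
        y = (X[:, 1] > 0).astype(int)
        sel = BSWiMSSelector(random_state=0).fit(X, y)
        assert sel.transform(X).shape == (30, len(sel.selected_idx_))


class TestRepeatedHoldout:
    def test_prediction_count_identity(self):
        X, y = planted_X(n=40)
        cfg = BenchmarkConfig(
            n_repeats=5, seed=0, include_ensemble=False,
            methods=[MethodSpec("W", "naive_bayes", "wilcoxon", 3)],
        )
        preds, _ = repeated_holdout(X, y, cfg)
        # 20% of 40 = 8 held-out subjects per repeat
        assert len(preds) == 5 * 8

    def test_splits_are_stratified(self):
        X, y = planted_X(n=40)
        cfg = BenchmarkConfig(
            n_repeats=8, seed=1, include_ensemble=False,
            methods=[MethodSpec("W", "naive_bayes", "wilcoxon", 3)],
        )
        preds, _ = repeated_holdout(X, y, cfg)
        for _, rep in preds.groupby("repeat"):
            assert abs(rep.y_true.sum() - 4) <= 1

    def test_separable_effect_high_accuracy(self):
        X, y = planted_X(effect=6.0, seed=7)
        cfg = BenchmarkConfig(
            n_repeats=10, seed=2, include_ensemble=False,
            methods=[MethodSpec("W", "svm", "wilcoxon", 3)],
        )
        preds, _ = repeated_holdout(X, y, cfg)
        assert (preds.y_pred == preds.y_true).mean() > 0.95

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(11)
        X, y = planted_X(effect=4.0, seed=11)
        y_perm = rng.permutation(y)
        cfg = BenchmarkConfig(
            n_repeats=25, seed=3, include_ensemble=False,
            methods=[MethodSpec("W", "naive_bayes", "wilcoxon", 3)],
        )
        preds, _ = repeated_holdout(X, y_perm, cfg)
        m = compute_metrics(preds, n_boot=50, seed=0)
        assert abs(m.loc["W", "roc_auc"] - 0.5) < 0.1

    def test_single_class_rejected(self):
        X, _ = planted_X()
        with pytest.raises(ValueError, match="both classes"):
            repeated_holdout(X, np.array(["MCIs"] * len(X)), BenchmarkConfig(n_repeats=2))

    def test_no_leakage_preprocessing_fit_on_train_only(self, monkeypatch):
        """Selector statistics must be computed on training rows only."""
        seen_sizes = []
        orig_fit = RankFilterSelector.fit

        def spy_fit(self, X, y):
            seen_sizes.append(len(y))
            return orig_fit(self, X, y)

        monkeypatch.setattr(RankFilterSelector, "fit", spy_fit)
        X, y = planted_X(n=40)
        cfg = BenchmarkConfig(
            n_repeats=3, seed=0, include_ensemble=False,
            methods=[MethodSpec("W", "naive_bayes", "wilcoxon", 3)],
        )
        repeated_holdout(X, y, cfg)
        assert seen_sizes == [32, 32, 32]  # never the full 40 subjects


class TestMetrics:
    @staticmethod
    def pool_from_confusion(tp, fn, tn, fp):
        rows = []
        sid = 0
        for y, p, count in ((1, 1, tp), (1, 0, fn), (0, 0, tn), (0, 1, fp)):
            for _ in range(count):
                rows.append(("m", 0, f"S{sid}", y, p, 0.9 if p else 0.1))
                sid += 1
        return pd.DataFrame(
            rows, columns=["method", "repeat", "subject", "y_true", "y_pred", "score"]
        )

    def test_study_confusion_counts_reproduce_printed_metrics(self):
        # sens 13/18, spec 14/22 -> accuracy 27/40, balanced error 0.321
        preds = self.pool_from_confusion(tp=13, fn=5, tn=14, fp=8)
        m = compute_metrics(preds, n_boot=10, seed=0).loc["m"]
        assert m.accuracy == pytest.approx(0.675)
        assert m.sensitivity == pytest.approx(13 / 18)
        assert m.specificity == pytest.approx(14 / 22)
        assert round(m.balanced_error, 3) == pytest.approx(0.321)

    def test_balanced_error_identity(self):
        preds = self.pool_from_confusion(tp=9, fn=3, tn=11, fp=7)
        m = compute_metrics(preds, n_boot=10, seed=0).loc["m"]
        assert m.balanced_error == pytest.approx(1 - (m.sensitivity + m.specificity) / 2)
        assert m.accuracy == pytest.approx((9 + 11) / 30)

    def test_perfect_predictions(self):
        preds = self.pool_from_confusion(tp=10, fn=0, tn=10, fp=0)
        m = compute_metrics(preds, n_boot=10, seed=0).loc["m"]
        assert m.accuracy == 1.0 and m.balanced_error == 0.0 and m.roc_auc == 1.0

    def test_auc_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(4)
        preds = self.pool_from_confusion(tp=8, fn=4, tn=9, fp=3)
        preds["score"] = rng.uniform(0, 1, len(preds))
        m1 = compute_metrics(preds, n_boot=5, seed=0).loc["m", "roc_auc"]
        preds2 = preds.assign(score=np.exp(5 * preds.score))
        m2 = compute_metrics(preds2, n_boot=5, seed=0).loc["m", "roc_auc"]
        assert m1 == pytest.approx(m2)

    def test_single_class_pool_errors(self):
        preds = self.pool_from_confusion(tp=5, fn=5, tn=0, fp=0)
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics(preds, n_boot=5)

    def test_ci_brackets_point_estimate(self):
        preds = self.pool_from_confusion(tp=13, fn=5, tn=14, fp=8)
        m = compute_metrics(preds, n_boot=200, seed=1).loc["m"]
        assert m.accuracy_lo <= m.accuracy <= m.accuracy_hi


class TestSelectionFrequency:
    def test_always_selected_feature_has_frequency_one(self):
        sels = {"m": [["a", "b"], ["a"], ["a", "c"]]}
        freq, tops = selection_frequency(sels)
        row = freq[(freq.method == "m") & (freq.feature == "a")]
        assert row.frequency.iloc[0] == 1.0
        assert tops["m"][0] == "a"

    def test_counting_identity(self):
        sels = {"m": [["a", "b"], ["b", "c"], ["a", "b", "c"]]}
        freq, _ = selection_frequency(sels)
        total = freq[freq.method == "m"].frequency.sum() * 3
        assert total == pytest.approx(sum(len(s) for s in sels["m"]))


class TestExperiments:
    @pytest.fixture(scope="class")
    def experiment_results(self, planted_effect_table):
        table, _, _ = planted_effect_table
        from t2asym.stats import screen_features

        pool = [
            c for c in screen_features(table).pool_columns if not c.startswith("score_")
        ]
        cfg = BenchmarkConfig(
            n_repeats=6, seed=4, n_boot=50,
            methods=[
                MethodSpec("LASSO", "lasso", None),
                MethodSpec("SVM", "svm", "mrmr", 8),
            ],
            include_ensemble=True,
        )
        return run_experiments(table, cfg, pool)

    def test_imaging_increment_improves_accuracy(self, experiment_results):
        acc1 = experiment_results["neuropsych"]["metrics"]["accuracy"]
        acc2 = experiment_results["neuropsych+imaging"]["metrics"]["accuracy"]
        assert (acc2 >= acc1).all()
        assert acc2.mean() > acc1.mean()

    def test_planted_pair_in_top_selected_features(self, experiment_results):
        tops = experiment_results["neuropsych+imaging"]["top_features"]
        for method, top in tops.items():
            assert any(f.startswith("hippocampus.") for f in top[:6]), method

    def test_reports_well_formed(self, experiment_results):
        for res in experiment_results.values():
            m = res["metrics"]
            assert {"accuracy", "sensitivity", "specificity",
                    "balanced_error", "roc_auc"} <= set(m.columns)
            assert {"LASSO", "SVM", "ENS"} == set(m.index)

    def test_identical_feature_sets_identical_reports(self, planted_effect_table):
        table, _, _ = planted_effect_table
        score_table = table[["group"] + [c for c in table.columns if c.startswith("score_")]]
        cfg = BenchmarkConfig(
            n_repeats=2, seed=9, n_boot=20, include_ensemble=False,
            methods=[MethodSpec("LASSO", "lasso", None)],
        )
        res = run_experiments(score_table, cfg, imaging_pool=[])
        pd.testing.assert_frame_equal(
            res["neuropsych"]["metrics"], res["neuropsych+imaging"]["metrics"]
        )
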