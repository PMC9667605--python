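"""GA feature selection, LOOCV scoring, SVM training, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from radsurv.errors import ConfigError, DomainError, SchemaError
from radsurv.model import (
    Chromosome,
    GAConfig,
    GeneticSVM,
    SVMConfig,
    decision_values,
    evolve,
    grid_search_svm,
    loocv_score,
    predict,
    roc_auc,
    train_final,
)


def _table(X, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


class TestLOOCV:
    def test_separable_feature_scores_one(self):
        X = _table(np.r_[-np.arange(1, 6), np.arange(1, 6)][:, None])
        y = np.r_[np.zeros(5), np.ones(5)]
        assert loocv_score(X, y, np.array([True])) == 1.0

    def test_manual_fold_by_fold_enumeration(self):
        # 1D points -2,-1,1,2 with labels 0,0,1,1: every fold still separates
        # at 0, so each held-out point is classified correctly.
        X = _table(np.array([[-2.0], [-1.0], [1.0], [2.0]]))
        y = np.array([0, 0, 1, 1])
        assert loocv_score(X, y, np.array([True]), SVMConfig(C=100.0)) == 1.0
        # single member of class 0: its fold trains on class 1 alone and must
        # predict class 1, so the held-out negative is always wrong:
        # TNR = 0, TPR = 1 -> balanced accuracy 1/2 by hand.
        y2 = np.array([0, 1, 1, 1])
        X2 = _table(np.array([[-9.0], [1.0], [2.0], [3.0]]))
        score = loocv_score(X2, y2, np.array([True]), SVMConfig(C=100.0))
        assert score == pytest.approx(0.5)

    def test_agrees_with_sklearn_loo_pipeline(self):
        # independent route: sklearn's LeaveOneOut + Pipeline machinery
        from sklearn.model_selection import LeaveOneOut
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 4))
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        preds = []
        for tr, te in LeaveOneOut().split(X):
            pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0, tol=1e-3))
            pipe.fit(X[tr], y[tr])
            preds.append(pipe.predict(X[te])[0])
        expected = balanced_accuracy_score(y, preds)
        assert loocv_score(_table(X), y, np.ones(4, bool)) == pytest.approx(expected)

    def test_null_labels_score_near_half(self):
        rng = np.random.default_rng(0)
        scores = []
        for seed in range(15):
            r = np.random.default_rng(seed)
            X = _table(r.standard_normal((40, 5)))
            y = r.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            scores.append(loocv_score(X, y, np.ones(5, bool)))
        assert 0.4 < np.mean(scores) < 0.6

    def test_single_class_and_empty_chromosome_rejected(self):
        X = _table(np.zeros((4, 2)))
        with pytest.raises(DomainError):
            loocv_score(X, np.ones(4), np.ones(2, bool))
        with pytest.raises(DomainError):
            loocv_score(X, np.array([0, 1, 0, 1]), np.zeros(2, bool))


class TestEvolve:
    def test_fixed_point_without_mutation_or_crossover(self, planted_cohort):
        table, labels, _ = planted_cohort
        ga = GAConfig(population_size=6, generations=3, mutation_rate=0.0,
                      crossover_rate=0.0, stagnation=10, seed=0,
                      local_search=False)
        rng = np.random.default_rng(0)
        # force an identical population by seeding init_prob=1 (all features)
        ga.init_prob = 1.0
        best, history = evolve(table, labels, ga, rng=rng)
        assert best.include.all()
        assert all(h["best_n_features"] == table.shape[1] for h in history)

    def test_same_seed_reproduces_history(self, planted_cohort):
        table, labels, _ = planted_cohort
        ga = GAConfig(population_size=10, generations=4, stagnation=10, seed=123)
        b1, h1 = evolve(table, labels, ga)
        b2, h2 = evolve(table, labels, ga)
        assert h1 == h2
        np.testing.assert_array_equal(b1.include, b2.include)

    def test_best_score_nondecreasing_with_elitism(self, planted_cohort):
        table, labels, _ = planted_cohort
        ga = GAConfig(population_size=12, generations=6, stagnation=10, seed=5)
        _, history = evolve(table, labels, ga)
        scores = [h["best_score"] for h in history]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_perfect_feature_is_selected(self):
        rng = np.random.default_rng(4)
        n = 30
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        X = rng.standard_normal((n, 8))
        X[:, 3] = y * 6 - 3 + 0.1 * rng.standard_normal(n)  # clean separator
        table = _table(X)
        ga = GAConfig(population_size=12, generations=8, stagnation=4, seed=4)
        best, _ = evolve(table, y, ga)
        assert best.include[3]
        assert best.score == 1.0

    def test_population_too_small_for_elitism(self):
        with pytest.raises(ConfigError):
            GAConfig(population_size=2, elite_fraction=0.9)


class TestGridSearchAndTraining:
    def test_singleton_grid_returned(self, planted_cohort):
        table, labels, _ = planted_cohort
        cfg, score = grid_search_svm(table, labels, list(table.columns[:4]),
                                     c_grid=(2.5,))
        assert cfg.C == 2.5

    def test_empty_grid_rejected(self, planted_cohort):
        table, labels, _ = planted_cohort
        with pytest.raises(ConfigError):
            grid_search_svm(table, labels, list(table.columns[:2]), c_grid=())

    def test_separable_data_reaches_score_one_and_small_c_tie(self):
        X = _table(np.r_[-np.arange(1, 8), np.arange(1, 8)][:, None])
        y = np.r_[np.zeros(7), np.ones(7)]
        cfg, score = grid_search_svm(X, y, ["f0"], c_grid=(1.0, 10.0, 100.0))
        assert score == 1.0
        assert cfg.C == 1.0  # all configs tie at 1.0; smallest C wins

    def test_two_point_hard_margin_boundary_at_zero(self):
        X = _table(np.array([[-1.0], [1.0]] * 3))
        y = np.array([0, 1] * 3)
        model = train_final(X, y, ["f0"], SVMConfig(C=1e4))
        test = _table(np.array([[-0.5], [0.0], [0.5]]))
        d = decision_values(model, test)
        assert d[1] == pytest.approx(0.0, abs=1e-6)
        assert d[0] < 0 < d[2]
        np.testing.assert_array_equal(predict(model, test), [0, 0, 1])

    def test_duplicated_dataset_same_hyperplane_when_separable(self):
        # hard-margin regime: the solution is determined by the margin
        # constraints alone, so duplicating every point changes nothing
        rng = np.random.default_rng(12)
        X = rng.standard_normal((16, 3))
        y = (X[:, 0] > 0).astype(int)
        y[:1] = 1 - y[:1] if len(np.unique(y)) < 2 else y[:1]
        X[:, 0] += (2 * y - 1) * 2.0  # widen the margin
        table = _table(X)
        sel = list(table.columns)
        m1 = train_final(table, y, sel, SVMConfig(C=1e4))
        m2 = train_final(pd.concat([table, table]), np.r_[y, y], sel, SVMConfig(C=1e4))
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-4)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-4)

    def test_decision_value_matches_dot_product(self):
        rng = np.random.default_rng(8)
        X = _table(rng.standard_normal((20, 2)), ["a", "b"])
        y = (X["a"] + X["b"] > 0).astype(int).to_numpy()
        model = train_final(X, y, ["a", "b"])
        point = _table(np.array([[0.3, -0.7]]), ["a", "b"])
        xs = (np.array([0.3, -0.7]) - model.center) / model.scale
        expected = (xs @ model.weights + model.bias) / np.linalg.norm(model.weights)
        assert decision_values(model, point)[0] == pytest.approx(expected)

    def test_missing_feature_column_is_schema_error(self, planted_cohort):
        table, labels, _ = planted_cohort
        model = train_final(table, labels, list(table.columns[:3]))
        with pytest.raises(SchemaError):
            decision_values(model, table.drop(columns=table.columns[0]))


class TestROC:
    def test_perfect_separation_auc_one(self):
        roc = roc_auc([-2, -1, 1, 2], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_all_ties_auc_half(self):
        roc = roc_auc([1.0] * 6, [0, 1, 0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_u_statistic(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.integers(0, 2, 12)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.standard_normal(12), 1)  # provoke ties
            u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
            expected = u / ((y == 1).sum() * (y == 0).sum())
            assert roc_auc(s, y).auc == pytest.approx(expected)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        a1 = roc_auc(s, y).auc
        a2 = roc_auc(np.exp(2 * s) + 5, y).auc
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestGeneticSVMFrontDoor:
    def test_fit_returns_results_with_summary(self, planted_cohort):
        table, labels, informative = planted_cohort
        ga = GAConfig(population_size=12, generations=6, stagnation=3, seed=2)
        res = GeneticSVM(table, labels, ga_config=ga).fit()
        assert 1 <= len(res.selected_features) <= table.shape[1]
        assert 0 <= res.loocv_score_ <= 1
        text = res.summary()
        assert "selected" in text and str(len(res.selected_features)) in text
        assert len(res.predict()) == len(labels)
        assert 0 <= res.roc().auc <= 1

    def test_json_roundtrip_preserves_decisions(self, planted_cohort, tmp_path):
        from radsurv.model import load_model_json

        table, labels, _ = planted_cohort
        ga = GAConfig(population_size=10, generations=4, stagnation=3, seed=6)
        res = GeneticSVM(table, labels, ga_config=ga).fit()
        res.to_json(tmp_path / "model.json")
        back = load_model_json(tmp_path / "model.json")
        np.testing.assert_allclose(
            decision_values(back, table), res.decision_values(), atol=1e-12
        )

    def test_from_dataframe_extracts_label_column(self, planted_cohort):
        table, labels, _ = planted_cohort
        df = table.copy()
        df["event"] = labels
        model = GeneticSVM.from_dataframe(df, "event")
        assert model.features.shape[1] == table.shape[1]
        np.testing.assert_array_equal(model.labels, labels)
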