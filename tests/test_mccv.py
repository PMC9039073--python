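import numpy as np
import pandas as pd
import pytest

import lipidrank as lr
from lipidrank.core import LipidDataError
from lipidrank.mccv import _metrics


def brute_force_auc(y, scores):
    """Oracle: proportion of (case, control) pairs correctly ordered,
    ties counted one half."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSplitPlan:
    def test_cohort_of_52_gives_test_size_10(self):
        labels = np.array([1] * 22 + [0] * 30)
        plan = lr.make_split_plan(labels, n_reps=20, seed=0)
        assert plan.n_reps == 20
        for rep in plan.reps:
            assert len(rep.test) == 10

    def test_partition_contract(self):
        labels = np.array([1] * 22 + [0] * 30)
        plan = lr.make_split_plan(labels, n_reps=10, seed=1)
        for rep in plan.reps:
            assert len(np.intersect1d(rep.train, rep.test)) == 0
            assert len(np.union1d(rep.train, rep.test)) == 52
            assert len(np.intersect1d(rep.inner_train, rep.inner_val)) == 0
            np.testing.assert_array_equal(
                np.union1d(rep.inner_train, rep.inner_val), np.sort(rep.train))

    def test_stratified_test_counts(self):
        labels = np.array([1] * 22 + [0] * 30)
        plan = lr.make_split_plan(labels, n_reps=50, stratify=True, seed=2)
        for rep in plan.reps:
            n_case = labels[rep.test].sum()
            assert abs(n_case - 4) <= 1
            assert abs((10 - n_case) - 6) <= 1

    def test_every_set_has_both_levels(self):
        labels = np.array([1] * 5 + [0] * 20)
        plan = lr.make_split_plan(labels, n_reps=30, seed=3)
        for rep in plan.reps:
            for s in (rep.train, rep.test, rep.inner_train, rep.inner_val):
                assert len(np.unique(labels[s])) == 2

    def test_deterministic_given_seed(self):
        labels = np.array([1] * 10 + [0] * 12)
        a = lr.make_split_plan(labels, n_reps=5, seed=4)
        b = lr.make_split_plan(labels, n_reps=5, seed=4)
        for ra, rb in zip(a.reps, b.reps):
            np.testing.assert_array_equal(ra.test, rb.test)
            np.testing.assert_array_equal(ra.inner_val, rb.inner_val)

    def test_group_too_small_is_error(self):
        labels = np.array([1] * 2 + [0] * 20)
        with pytest.raises(LipidDataError, match="too small"):
            lr.make_split_plan(labels, n_reps=5, seed=0)


class TestAUC:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 15)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            assert np.isclose(lr.auc_score(y, scores),
                              brute_force_auc(y, scores))

    def test_all_tied_scores_give_half(self):
        assert lr.auc_score(np.array([1, 1, 0, 0]),
                            np.array([0.3, 0.3, 0.3, 0.3])) == 0.5

    def test_metrics_against_confusion_matrix_oracle(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        proba = np.array([0.9, 0.4, 0.6, 0.2, 0.7, 0.1, 0.3])
        m = _metrics(y, proba)
        # by hand: TP=2 FN=1 TN=3 FP=1
        assert m["accuracy"] == pytest.approx(5 / 7)
        assert m["tpr"] == pytest.approx(2 / 3)
        assert m["tnr"] == pytest.approx(3 / 4)
        assert m["auc"] == pytest.approx(brute_force_auc(y, proba))


class TestTuning:
    def test_singleton_grid_returns_that_config(self, spiked_cohort):
        m, meta, _ = spiked_cohort
        ft = lr.build_feature_table(m, meta)
        plan = lr.make_split_plan(ft.y, n_reps=1, seed=0)
        cfg = lr.RFConfig(n_estimators=10)
        rep = plan.reps[0]
        out = lr.tune_hyperparameters(ft.X, ft.y, [cfg], rep.inner_train,
                                      rep.inner_val, seed=0)
        assert out == cfg

    def test_deterministic_choice(self, spiked_cohort):
        m, meta, _ = spiked_cohort
        ft = lr.build_feature_table(m, meta)
        plan = lr.make_split_plan(ft.y, n_reps=1, seed=1)
        grid = [lr.RFConfig(n_estimators=t) for t in (10, 30)]
        rep = plan.reps[0]
        a = lr.tune_hyperparameters(ft.X, ft.y, grid, rep.inner_train,
                                    rep.inner_val, seed=5)
        b = lr.tune_hyperparameters(ft.X, ft.y, grid, rep.inner_train,
                                    rep.inner_val, seed=5)
        assert a == b


class TestEvaluateAndRank:
    def test_separable_cohort_scores_high_auc(self, small_tax, tiny_grid):
        effects = lr.EffectSpec(class_effects={"A": 3.0})
        m, meta, _ = lr.simulate_cohort(small_tax, 15, 15, effects=effects,
                                        noise_sd=0.5, seed=7)
        ft = lr.build_feature_table(m, meta)
        plan = lr.make_split_plan(ft.y, n_reps=10, seed=7)
        report = lr.evaluate_classifier(ft, plan, tiny_grid)
        assert report.mean_metrics["auc"] >= 0.95

    def test_metrics_within_unit_interval(self, null_cohort, tiny_grid):
        m, meta, _ = null_cohort
        ft = lr.build_feature_table(m, meta)
        plan = lr.make_split_plan(ft.y, n_reps=5, seed=0)
        report = lr.evaluate_classifier(ft, plan, tiny_grid)
        vals = report.per_rep[["accuracy", "tpr", "tnr", "auc"]].to_numpy()
        assert ((0 <= vals) & (vals <= 1)).all()
        assert len(report.per_rep) == 5

    def test_class_level_ranking_has_36_variables(self, default_tax,
                                                  tiny_grid):
        m, meta, _ = lr.simulate_cohort(default_tax, seed=0)
        cm = lr.aggregate_to_classes(m, default_tax)
        ft = lr.build_feature_table(cm, meta)
        assert ft.X.shape[1] == 36
        plan = lr.make_split_plan(ft.y, n_reps=3, seed=0)
        report = lr.rank_variables(ft, plan, tiny_grid)
        assert len(report.importance) == 36
        assert {"age", "sex_female"} <= set(report.importance["feature"])

    def test_single_informative_variable_ranks_first(self, small_tax,
                                                     tiny_grid):
        effects = lr.EffectSpec(species_effects={"B.30.0": 3.0})
        m, meta, _ = lr.simulate_cohort(small_tax, 15, 15, effects=effects,
                                        noise_sd=0.4, seed=3)
        ft = lr.build_feature_table(m, meta)
        plan = lr.make_split_plan(ft.y, n_reps=10, seed=3)
        report = lr.rank_variables(ft, plan, tiny_grid)
        assert report.importance.iloc[0]["feature"] == "B.30.0"

    def test_mean_importances_sum_to_one(self, null_cohort, tiny_grid):
        m, meta, _ = null_cohort
        ft = lr.build_feature_table(m, meta)
        plan = lr.make_split_plan(ft.y, n_reps=4, seed=1)
        report = lr.rank_variables(ft, plan, tiny_grid)
        assert report.importance["mean_importance"].sum() == pytest.approx(1.0)
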