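import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neuropathnet.evaluation import (
    CVPlan,
    best_node_correlation,
    dataset_subset_experiment,
    group_compare,
    neuropathology_score,
    one_minus_r2cv,
    run_nested_cv,
    select_final_config,
    unsupervised_baseline_embedding,
)
from neuropathnet.models import MultiTaskNeuralRegressor


class TestErrorMetric:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.random(20)
        assert one_minus_r2cv(y, y) == 0.0

    def test_test_mean_predictor_is_exactly_one(self, rng):
        y = rng.random(50)
        pred = np.full(50, y.mean())
        assert one_minus_r2cv(y, pred) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_case(self):
        truth = np.array([0.0, 0.5, 1.0])
        pred = np.array([0.1, 0.5, 0.9])
        assert one_minus_r2cv(truth, pred) == pytest.approx(0.04)

    def test_masked_cells_excluded_first(self, rng):
        y = np.array([0.0, np.nan, 1.0, 0.5])
        pred = np.array([0.0, 99.0, 1.0, 0.5])
        assert one_minus_r2cv(y, pred) == 0.0

    def test_zero_variance_reported_missing_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = one_minus_r2cv(np.array([0.3, 0.3, 0.3]), np.array([0.1, 0.2, 0.3]))
        assert np.isnan(out)
        assert any("variance" in r.message for r in caplog.records)

    def test_train_mean_predictor_at_least_one_in_expectation(self, rng):
        vals = []
        for _ in range(200):
            tr, te = rng.random(30), rng.random(30)
            vals.append(one_minus_r2cv(te, np.full(30, tr.mean())))
        assert np.mean(vals) >= 1.0


def _factory(cfg):
    return MultiTaskNeuralRegressor(
        shared_widths=(12, 6), branch_widths=(4,), n_tasks=2, epochs=8,
        random_state=0, **cfg,
    )


def _toy_multitask(rng, n=100):
    X = rng.standard_normal((n, 8))
    w = rng.standard_normal((8, 2)) * 0.4
    Y = X @ w + rng.standard_normal((n, 2)) * 0.2
    Y[rng.random(Y.shape) < 0.2] = np.nan
    return X, Y


class TestNestedCV:
    def test_single_config_grid_reduces_to_plain_cv(self, rng):
        X, Y = _toy_multitask(rng)
        res = run_nested_cv(X, Y, [{}], plan=CVPlan(n_outer=3, n_inner=2, seed=1),
                            estimator_factory=_factory)
        assert res.config_errors.shape == (3, 1)
        assert len(res.selected_configs) == 3
        assert set(res.outer["round"]) == {0, 1, 2}

    def test_planted_best_config_selected(self, rng):
        X, Y = _toy_multitask(rng, n=120)
        grid = [{"learning_rate": 1e-3}, {"learning_rate": 1e-9}]
        res = run_nested_cv(X, Y, grid, plan=CVPlan(n_outer=5, n_inner=3, seed=0),
                            estimator_factory=_factory)
        n_good = sum(cfg["learning_rate"] == 1e-3 for cfg in res.selected_configs)
        assert n_good >= 4

    def test_individual_grouping_never_splits_an_individual(self, rng):
        X, Y = _toy_multitask(rng, n=80)
        groups = np.repeat(np.arange(40), 2)
        plan = CVPlan(n_outer=4, n_inner=2, grouping="by_individual", seed=0)
        from sklearn.model_selection import GroupKFold

        cv = GroupKFold(n_splits=4, shuffle=True, random_state=0)
        for tr, te in cv.split(X, groups=groups):
            assert not set(groups[tr]) & set(groups[te])
        res = run_nested_cv(X, Y, [{}], plan=plan, groups=groups,
                            estimator_factory=_factory)
        assert not res.outer.empty

    def test_outer_test_folds_partition_samples(self, rng):
        X, Y = _toy_multitask(rng)
        res = run_nested_cv(X, Y, [{}], plan=CVPlan(n_outer=4, n_inner=2, seed=3),
                            estimator_factory=_factory)
        covered = np.concatenate([te for te, _ in res.predictions.values()])
        assert sorted(covered) == list(range(len(X)))


class TestFinalConfigSelection:
    def test_dominating_config_selected(self):
        errors = np.array([[0.1, 0.5], [0.2, 0.6], [0.1, 0.4]])
        idx, cfg = select_final_config(errors, [{"a": 1}, {"a": 2}])
        assert idx == 0 and cfg == {"a": 1}

    def test_hand_rank_arithmetic(self):
        # ranks A=[1,2,1,2,1], B=[2,1,2,1,2] -> A wins on mean rank 1.4 < 1.6
        errors = np.array(
            [[0.1, 0.2], [0.3, 0.2], [0.1, 0.2], [0.3, 0.2], [0.1, 0.2]]
        )
        idx, _ = select_final_config(errors, [{"c": "A"}, {"c": "B"}])
        assert idx == 0

    def test_exact_tie_breaks_by_grid_order(self):
        errors = np.array([[0.2, 0.2], [0.2, 0.2]])
        idx, _ = select_final_config(errors, [{"c": "first"}, {"c": "second"}])
        assert idx == 0

    def test_rank_tie_broken_by_lower_mean_error(self):
        # equal mean ranks but config 2 has lower mean error
        errors = np.array([[0.1, 0.4], [0.4, 0.1]])
        idx, _ = select_final_config(errors, [{"c": 1}, {"c": 2}])
        assert idx == 0  # mean errors equal -> grid order
        errors = np.array([[0.1, 0.5], [0.5, 0.05]])
        idx, _ = select_final_config(errors, [{"c": 1}, {"c": 2}])
        assert idx == 1


class TestNeuropathologyScore:
    def test_single_phenotype_rank_definition(self):
        scores = neuropathology_score(np.array([0.2, 0.4, 0.9]), ["d"] * 3)
        np.testing.assert_allclose(scores, [0.0, 0.5, 1.0])

    def test_reversed_orders_cancel(self):
        preds = np.column_stack([[0.1, 0.2, 0.3], [0.3, 0.2, 0.1]])
        scores = neuropathology_score(preds, ["d"] * 3)
        np.testing.assert_allclose(scores, 0.5)

    def test_ties_match_brute_force_oracle(self):
        preds = np.array(
            [[0.1, 0.5], [0.1, 0.2], [0.7, 0.2], [0.3, 0.9], [0.9, 0.9]]
        )
        def brute(col):
            n = len(col)
            pct = np.empty(n)
            for i, v in enumerate(col):
                less = sum(1 for u in col if u < v)
                eq = sum(1 for u in col if u == v)
                rank = less + (eq + 1) / 2  # mean rank over ties
                pct[i] = (rank - 1) / (n - 1)
            return pct

        expected = (brute(preds[:, 0]) + brute(preds[:, 1])) / 2
        np.testing.assert_allclose(
            neuropathology_score(preds, ["d"] * 5), expected
        )

    def test_within_dataset_ranking(self):
        preds = np.array([0.1, 0.9, 0.2, 0.8])
        scores = neuropathology_score(preds, ["a", "a", "b", "b"])
        np.testing.assert_allclose(scores, [0, 1, 0, 1])

    def test_single_sample_dataset_scores_half(self):
        scores = neuropathology_score(np.array([0.3, 0.1, 0.9]), ["a", "b", "b"])
        assert scores[0] == 0.5

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=10))
    def test_invariance_under_strictly_monotone_transforms(self, values):
        preds = np.asarray(values)[:, None]
        base = neuropathology_score(preds, ["d"] * len(values))
        warped = neuropathology_score(np.expm1(3 * preds) + preds, ["d"] * len(values))
        np.testing.assert_array_equal(base, warped)

    def test_scores_lie_in_unit_interval(self, rng):
        preds = rng.random((40, 6))
        scores = neuropathology_score(preds, rng.choice(["a", "b"], 40))
        assert scores.min() >= 0 and scores.max() <= 1


class TestGroupCompare:
    def test_identical_groups_are_indistinguishable(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        t, p = group_compare(x, ["a", "a", "a", "b", "b", "b"])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_detected(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200) + 1.0
        t, p = group_compare(
            np.concatenate([a, b]), ["a"] * 200 + ["b"] * 200
        )
        assert abs(t) > 5

    def test_pooled_textbook_case(self):
        t, p = group_compare(
            np.array([1.0, 2, 3, 4, 5, 6]),
            ["a", "a", "a", "b", "b", "b"],
            pooled=True,
        )
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            group_compare(np.array([1.0, 2, 3]), ["a", "b", "b"])


class TestNodeCorrelation:
    def test_perfect_correlate_selected_and_maximal(self, rng):
        n = 100
        y_tr, y_te = rng.random(n), rng.random(n)
        E_tr = rng.standard_normal((n, 20))
        E_te = rng.standard_normal((n, 20))
        E_tr[:, 7] = y_tr
        E_te[:, 7] = y_te
        out = best_node_correlation(E_tr, E_te, y_tr, y_te)
        assert out["node"] == 7
        assert out["neg_log10_q"] > 10

    def test_pure_noise_embedding_reports_no_signal(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            y_tr, y_te = r.random(100), r.random(100)
            E_tr, E_te = r.standard_normal((100, 100)), r.standard_normal((100, 100))
            vals.append(best_node_correlation(E_tr, E_te, y_tr, y_te)["neg_log10_q"])
        assert np.median(vals) <= 1.0

    def test_matches_direct_recomputation_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        n = 200
        y_tr, y_te = rng.standard_normal(n), rng.standard_normal(n)
        E_tr = rng.standard_normal((n, 15))
        E_te = rng.standard_normal((n, 15))
        E_tr[:, 3] = y_tr + rng.standard_normal(n) / 2  # SNR 2
        E_te[:, 3] = y_te + rng.standard_normal(n) / 2
        out = best_node_correlation(E_tr, E_te, y_tr, y_te)
        ps = np.array([stats.pearsonr(E_te[:, j], y_te).pvalue for j in range(15)])
        q = multipletests(ps, method="fdr_bh")[1]
        sel = np.argmin([stats.pearsonr(E_tr[:, j], y_tr).pvalue for j in range(15)])
        assert out["node"] == sel
        assert out["neg_log10_q"] == pytest.approx(-np.log10(q[sel]), rel=1e-6)


class TestUnsupervisedEmbeddings:
    def test_pca_of_low_rank_data_has_null_trailing_columns(self, rng):
        X = rng.standard_normal((40, 5)) @ rng.standard_normal((5, 30))
        E = unsupervised_baseline_embedding(X, method="pca", dim=10)
        assert np.abs(E[:, 6:]).max() < 1e-8

    def test_kmeans_with_one_cluster_per_sample(self, rng):
        X = rng.standard_normal((15, 4)) * 10
        E = unsupervised_baseline_embedding(X, method="kmeans", dim=15)
        assert E.shape == (15, 15)
        assert (np.isclose(E, 0, atol=1e-5).sum(axis=1) >= 1).all()

    def test_fixed_seed_reproducible(self, rng):
        X = rng.standard_normal((30, 6))
        a = unsupervised_baseline_embedding(X, "kmeans", dim=5, random_state=1)
        b = unsupervised_baseline_embedding(X, "kmeans", dim=5, random_state=1)
        np.testing.assert_array_equal(a, b)


class TestSubsetExperiment:
    def test_target_only_subset_runs_and_reports_all_tasks(self, rng):
        n = 90
        X = rng.standard_normal((n, 6))
        Y = rng.random((n, 2))
        cohort = np.array(["A"] * 45 + ["B"] * 45)
        df = dataset_subset_experiment(
            X, Y, cohort, "A", [["A"], ["A", "B"]], {},
            estimator_factory=_factory, n_rounds=3,
        )
        assert set(df["subset"]) == {"A", "A+B"}
        assert len(df) == 2 * 3 * 2

    def test_empty_subset_rejected(self, rng):
        X, Y = rng.standard_normal((20, 3)), rng.random((20, 2))
        with pytest.raises(ValueError, match="empty"):
            dataset_subset_experiment(
                X, Y, np.array(["A"] * 20), "A", [[]], {},
                estimator_factory=_factory, n_rounds=2,
            )
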