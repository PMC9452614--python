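"""CV plan, metrics, DeLong/McNemar, threshold sweeps and the benchmark grid."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lipomics.evaluate import (
    CLASSIFIER_NAMES,
    FAST_GRIDS,
    auc_mann_whitney,
    binary_metrics,
    delong_test,
    delong_variance,
    make_cv_plan,
    paired_tests,
    run_benchmark,
    threshold_sweep,
    train_classifier,
)

from oracles import auc_rank_oracle


def _case_table(n0=40, n1=45):
    return pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(n0 + n1)],
            "label": [0] * n0 + [1] * n1,
        }
    )


class TestCVPlan:
    def test_fold_sizes_pigeonhole(self):
        plan = make_cv_plan(_case_table(40, 45), k=10, seed=0)
        sizes = pd.Series(list(plan.folds.values())).value_counts()
        assert set(sizes) <= {8, 9}
        assert sizes.sum() == 85

    def test_rows_of_same_case_share_fold(self):
        t = _case_table(10, 10)
        rows = pd.concat([t, t, t], ignore_index=True)  # 3 rows per case
        plan = make_cv_plan(rows, k=5, seed=1)
        f = plan.fold_of(rows.case_id)
        for cid, grp in pd.DataFrame({"c": rows.case_id, "f": f}).groupby("c"):
            assert grp.f.nunique() == 1

    def test_deterministic_given_seed(self):
        t = _case_table(20, 20)
        assert make_cv_plan(t, 5, seed=3).folds == make_cv_plan(t, 5, seed=3).folds
        assert make_cv_plan(t, 5, seed=3).folds != make_cv_plan(t, 5, seed=4).folds

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            make_cv_plan(_case_table(5, 40), k=10, seed=0)

    def test_stratification_within_one_case(self):
        plan = make_cv_plan(_case_table(30, 30), k=6, seed=0)
        t = _case_table(30, 30)
        t["fold"] = plan.fold_of(t.case_id)
        per_fold = t.groupby("fold").label.mean()
        assert (np.abs(per_fold - 0.5) <= 0.11).all()


class TestAUC:
    def test_perfect_separation(self):
        assert auc_mann_whitney([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_mann_whitney([0.4] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_undefined(self):
        assert np.isnan(auc_mann_whitney([0.1, 0.2], [1, 1]))

    def test_matches_rank_sum_oracle_and_sklearn(self, rng):
        scores = rng.random(200).round(2)  # rounding forces ties
        labels = rng.integers(0, 2, 200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        a = auc_mann_whitney(scores, labels)
        assert a == pytest.approx(auc_rank_oracle(scores, labels), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestBinaryMetricsAndSweep:
    def test_worked_example(self):
        m = binary_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], threshold=0.5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        assert m["auc"] == 1.0
        assert m["confusion"] == {"tp": 2, "tn": 2, "fp": 0, "fn": 0}

    def test_sweep_monotone_and_endpoints(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:5] = 1
        labels[5:10] = 0
        sweep, _ = threshold_sweep(scores, labels)
        sens = sweep.sensitivity.to_numpy()
        assert (np.diff(sens) <= 1e-12).all()
        assert sweep.sensitivity.iloc[0] == 1.0 and sweep.specificity.iloc[0] == 0.0

    def test_perfect_scorer_f1_between_class_ranges(self):
        scores = [0.05, 0.1, 0.15, 0.85, 0.9, 0.95]
        labels = [0, 0, 0, 1, 1, 1]
        sweep, _ = threshold_sweep(scores, labels)
        mid = sweep[(sweep.threshold > 0.2) & (sweep.threshold < 0.8)]
        assert (mid.f1_malignant == 1.0).all()
        assert (mid.f1_benign == 1.0).all()

    def test_operating_point_targets_full_sensitivity(self, rng):
        scores = np.concatenate([rng.uniform(0, 0.6, 30), rng.uniform(0.3, 1.0, 30)])
        labels = np.array([0] * 30 + [1] * 30)
        sweep, op = threshold_sweep(scores, labels, sensitivity_target=1.0)
        row = sweep[np.isclose(sweep.threshold, op)].iloc[0]
        assert row.sensitivity == 1.0


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.random(40)
        y = np.array([0, 1] * 20)
        res = delong_test(s, s, y)
        assert res["p"] == 1.0 and res["degenerate"]

    def test_antisymmetric_scores_strongly_different(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 30 + [1] * 30)
        s = np.concatenate([rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1.0, 30)])
        res = delong_test(s, 1 - s, y)
        assert res["auc_a"] == 1.0 and res["auc_b"] == 0.0
        assert res["p"] < 0.001

    def test_variance_close_to_bootstrap(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        s = np.clip(0.5 + 0.25 * (y - 0.5) + rng.normal(0, 0.2, n), 0, 1)
        v_delong = delong_variance(s, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(set(y[idx])) < 2:
                continue
            boots.append(auc_mann_whitney(s[idx], y[idx]))
        v_boot = np.var(boots, ddof=1)
        assert v_delong == pytest.approx(v_boot, rel=0.15)


class TestPairedTests:
    def test_mcnemar_hand_formula(self):
        # b = 10, c = 2 discordant pairs -> (|10-2|-1)^2/12 = 49/12
        labels = np.zeros(40, dtype=int)
        preds_a = np.zeros(40, dtype=int)
        preds_b = np.zeros(40, dtype=int)
        preds_b[:10] = 1   # A correct, B wrong: b = 10
        preds_a[10:12] = 1  # A wrong, B correct: c = 2
        res = paired_tests(preds_a, preds_b, labels)
        assert res["mcnemar_statistic"] == pytest.approx(49 / 12)
        assert res["mcnemar_p"] == pytest.approx(0.0433, abs=0.002)

    def test_identical_predictions_degenerate(self):
        p = np.array([0, 1, 1, 0, 1])
        res = paired_tests(p, p, np.array([0, 1, 0, 0, 1]))
        assert res["mcnemar_p"] == 1.0 and res["mcnemar_degenerate"]

    def test_symmetry_in_a_and_b(self, rng):
        y = rng.integers(0, 2, 50)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        r1 = paired_tests(a, b, y)
        r2 = paired_tests(b, a, y)
        assert r1["mcnemar_p"] == pytest.approx(r2["mcnemar_p"])
        assert r1["chi2_p"] == pytest.approx(r2["chi2_p"], nan_ok=True)


class TestClassifiers:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_separable_toy_problem_perfect_training_auc(self, name, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        est = train_classifier(name, X, y, grid=FAST_GRIDS[name], seed=0)
        p = est.predict_proba(X)[:, 1]
        assert auc_mann_whitney(p, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier("LR", np.zeros((5, 2)), np.ones(5))

    def test_standardizer_learned_on_training_rows_only(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        est = train_classifier("LR", X, y, grid=FAST_GRIDS["LR"], seed=0)
        scaler = est.named_steps["scale"]
        np.testing.assert_allclose(scaler.mean_, X.mean(axis=0))
        # scoring new rows never mutates the fitted statistics
        est.predict_proba(rng.normal(10, 5, size=(10, 4)))
        np.testing.assert_allclose(scaler.mean_, X.mean(axis=0))


class TestBenchmarkGrid:
    def test_grid_shape_and_sane_rows(self, tiny_feature_table):
        report = run_benchmark(tiny_feature_table, k=3, grids=FAST_GRIDS, seed=0)
        assert len(report["rows"]) == 8  # 4 classifiers x {raw, combat}
        for row in report["rows"]:
            assert 0.0 <= row["auc_mean"] <= 1.0
            assert row["auc_sd"] >= 0.0
        assert len(report["comparisons"]) == 4
        for c in report["comparisons"]:
            assert 0.0 <= c["p"] <= 1.0

    def test_training_artifacts_do_not_depend_on_held_out_rows(self, tiny_feature_table):
        """Leakage audit: mutating a held-out case must not change the
        fold model's scores for the other held-out cases."""
        from lipomics.combat import NON_FEATURE_COLUMNS
        from lipomics.evaluate import cross_validated_scores

        t = tiny_feature_table.copy()
        plan = make_cv_plan(t, k=3, seed=0)
        base = cross_validated_scores(t, plan, "LR", harmonize=True, grids=FAST_GRIDS, seed=0)
        fold = plan.fold_of(t.case_id)
        feats = [c for c in t.columns if c not in NON_FEATURE_COLUMNS]
        victim = t.index[fold == 0][0]
        t.loc[victim, feats] = t.loc[victim, feats] * 3.0 + 11.0
        mutated = cross_validated_scores(t, plan, "LR", harmonize=True, grids=FAST_GRIDS, seed=0)
        keep = base.case_id != t.loc[victim, "case_id"]
        keep0 = base.fold == 0
        np.testing.assert_allclose(
            base.score[keep & keep0].to_numpy(), mutated.score[keep & keep0].to_numpy(), atol=1e-12
        )
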