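"""Split, screening, LASSO Radscore, ROC and DCA contracts."""

import numpy as np
import pandas as pd
import pytest

from kinhet import (
    CohortSpec,
    InvalidParameterError,
    ModelError,
    ScreeningError,
    SplitSpec,
    compute_radscore,
    decision_curve,
    evaluate_roc,
    fit_lasso_cv,
    run_subtype_task,
    screen_features,
    simulate_feature_cohort,
    split_cohort,
    univariate_roc,
)
from kinhet.models import RadscoreModel, radscore_probability


class TestSplit:
    def test_124_patients_split_87_37(self):
        y = np.array([0] * 57 + [1] * 67)
        tr, te = split_cohort(y, SplitSpec(seed=0))
        assert (len(tr), len(te)) == (87, 37)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 124

    def test_small_cohort_rounding(self):
        y = np.array([0] * 5 + [1] * 5)
        tr, te = split_cohort(y, SplitSpec(seed=3))
        assert (len(tr), len(te)) == (7, 3)

    def test_stratification_preserves_class_fractions(self):
        y = np.array([0] * 57 + [1] * 67)
        tr, _ = split_cohort(y, SplitSpec(seed=5))
        frac = y[tr].mean()
        assert abs(frac - y.mean()) <= 1.5 / len(tr)

    def test_seeded_determinism(self):
        y = np.array([0] * 30 + [1] * 30)
        a = split_cohort(y, SplitSpec(seed=11))
        b = split_cohort(y, SplitSpec(seed=11))
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_class_rejected(self):
        with pytest.raises(ModelError):
            split_cohort(np.array([0, 0, 0, 1]), SplitSpec())


class TestScreening:
    def test_constant_column_removed(self, rng):
        t = pd.DataFrame({"a": rng.random(40), "b": np.ones(40)})
        y = np.repeat([0, 1], 20)
        t["a"] += y * 3  # make 'a' survive the rank filter
        res = screen_features(t, y)
        assert res.removed["b"] == "zero variance"
        assert "a" in res.kept

    def test_informative_columns_survive(self):
        # effect 2.0: all 5 informative columns should pass the rank test
        coh = simulate_feature_cohort(CohortSpec(seed=4, feature_effect=2.0))
        res = screen_features(coh.table, coh.labels)
        assert set(coh.informative) <= set(res.kept)

    def test_filter_disabled_keeps_noise_columns(self, rng):
        t = pd.DataFrame(rng.random((30, 8)), columns=list("abcdefgh"))
        t["const"] = 5.0
        y = np.repeat([0, 1], 15)
        res = screen_features(t, y, rank_filter=False)
        assert res.kept == list("abcdefgh")

    def test_all_removed_raises(self):
        t = pd.DataFrame({"a": np.ones(20), "b": np.zeros(20)})
        with pytest.raises(ScreeningError):
            screen_features(t, np.repeat([0, 1], 10))


class TestLasso:
    def test_separable_data_training_auc_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 40)
        x = rng.standard_normal((80, 10))
        x[:, 0] += y * 10  # fully separable on one column
        t = pd.DataFrame(x, columns=[f"f{j}" for j in range(10)])
        model = fit_lasso_cv(t, y, seed=0)
        auc = evaluate_roc(compute_radscore(model, t), y).auc
        assert auc == 1.0
        assert "f0" in model.selected

    def test_huge_penalty_gives_intercept_only(self, rng):
        y = np.repeat([0, 1], 30)
        t = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
        model = fit_lasso_cv(t, y, seed=0)
        # emulate the lambda -> infinity limit directly
        big = RadscoreModel(
            feature_names=model.feature_names,
            coefficients=np.zeros_like(model.coefficients),
            intercept=model.intercept,
            lambda_=np.inf,
            feature_means=model.feature_means,
            feature_sds=model.feature_sds,
            cv_deviance=model.cv_deviance,
        )
        scores = compute_radscore(big, t)
        assert np.ptp(scores) == 0.0
        assert big.selected == []

    def test_informative_support_recovered(self):
        hits = 0
        for seed in range(10):
            coh = simulate_feature_cohort(CohortSpec(seed=seed, feature_effect=2.0))
            model = fit_lasso_cv(coh.table, coh.labels, seed=seed)
            hits += len(set(model.selected) & set(coh.informative)) >= 3
        assert hits >= 9  # >= 3 of 5 informative columns in ~all seeds

    def test_single_class_rejected(self, rng):
        t = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        with pytest.raises(ModelError):
            fit_lasso_cv(t, np.zeros(20, int))

    def test_radscore_arithmetic_and_monotonicity(self):
        model = RadscoreModel(
            feature_names=["x"],
            coefficients=np.array([2.0]),
            intercept=0.0,
            lambda_=0.1,
            feature_means=np.array([0.0]),
            feature_sds=np.array([1.0]),
            cv_deviance=pd.DataFrame(),
        )
        t = pd.DataFrame({"x": [1.5, -1.0, 0.0]})
        scores = compute_radscore(model, t)
        np.testing.assert_allclose(scores, [3.0, -2.0, 0.0])
        probs = radscore_probability(model, t)
        assert (np.argsort(scores) == np.argsort(probs)).all()

    def test_missing_feature_rejected(self):
        model = RadscoreModel(
            feature_names=["x", "y"],
            coefficients=np.array([1.0, 1.0]),
            intercept=0.0,
            lambda_=0.1,
            feature_means=np.zeros(2),
            feature_sds=np.ones(2),
            cv_deviance=pd.DataFrame(),
        )
        with pytest.raises(ModelError):
            compute_radscore(model, pd.DataFrame({"x": [1.0]}))

    def test_no_test_set_leakage(self):
        # permuting rows outside the training set never changes the model
        coh = simulate_feature_cohort(CohortSpec(seed=8, feature_effect=1.0))
        tr, te = split_cohort(coh.labels, SplitSpec(seed=8))
        table2 = coh.table.copy()
        table2.iloc[te] = table2.iloc[np.random.default_rng(0).permutation(te)].to_numpy()
        m1 = fit_lasso_cv(coh.table.iloc[tr], coh.labels[tr], seed=8)
        m2 = fit_lasso_cv(table2.iloc[tr], coh.labels[tr], seed=8)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        assert m1.lambda_ == m2.lambda_


class TestRoc:
    def test_pair_counting_example(self):
        # one discordant pair of four -> AUC 0.75
        s = evaluate_roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert s.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        s = evaluate_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert s.auc == 1.0
        assert s.sensitivity == 1.0 and s.specificity == 1.0
        assert s.accuracy == 1.0

    def test_permuted_labels_auc_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.permutation(np.repeat([0, 1], 1000))
        assert abs(evaluate_roc(scores, labels).auc - 0.5) < 0.03

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(100)
        y = (rng.random(100) < 0.4).astype(int)
        a = evaluate_roc(scores, y).auc
        b = evaluate_roc(np.exp(5 * scores), y).auc
        assert a == pytest.approx(b)

    def test_youden_cutoff_attains_max(self, rng):
        scores = rng.random(60)
        y = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        s = evaluate_roc(scores, y)
        best = max(
            ((scores >= c) & (y == 1)).sum() / (y == 1).sum()
            + ((scores < c) & (y == 0)).sum() / (y == 0).sum()
            - 1
            for c in scores
        )
        assert s.sensitivity + s.specificity - 1 == pytest.approx(best)

    def test_ci_contains_auc_and_is_ordered(self, rng):
        scores = rng.random(50)
        y = np.repeat([0, 1], 25)
        s = evaluate_roc(scores, y)
        assert 0 <= s.ci_low <= s.auc <= s.ci_high <= 1

    def test_one_class_rejected(self):
        with pytest.raises(ModelError):
            evaluate_roc([1, 2, 3], [1, 1, 1])


class TestUnivariateRoc:
    def test_constant_parameter_flagged(self):
        s = univariate_roc(np.ones(20), np.repeat([0, 1], 10))
        assert s.auc == pytest.approx(0.5)
        assert s.degenerate

    def test_informative_parameter(self, rng):
        y = np.repeat([0, 1], 50)
        s = univariate_roc(y + rng.normal(0, 0.1, 100), y)
        assert s.auc > 0.95

    def test_orientation_flip_symmetry(self, rng):
        y = np.repeat([0, 1], 50)
        vals = y + rng.normal(0, 0.5, 100)
        a = univariate_roc(vals, y)
        b = univariate_roc(-vals, y)
        assert a.auc == pytest.approx(b.auc)
        assert b.flipped and not a.flipped


class TestDecisionCurve:
    def test_treat_none_is_zero_and_treat_all_formula(self, rng):
        y = np.repeat([0, 1], 50)
        probs = np.clip(rng.random(100), 0.01, 0.99)
        dca = decision_curve(probs, y)
        np.testing.assert_allclose(dca["treat_none"], 0.0)
        pt = dca["threshold"].to_numpy()
        prev = y.mean()
        np.testing.assert_allclose(
            dca["treat_all"], prev - (1 - prev) * pt / (1 - pt)
        )

    def test_treat_all_zero_at_half_for_balanced_cohort(self):
        y = np.repeat([0, 1], 10)
        dca = decision_curve(np.full(20, 0.5), y, thresholds=[0.5])
        assert dca["treat_all"].iloc[0] == pytest.approx(0.0)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.repeat([0, 1], 25)
        probs = np.where(y == 1, 0.99, 0.01)
        dca = decision_curve(probs, y, thresholds=np.arange(0.02, 0.99, 0.05))
        np.testing.assert_allclose(dca["net_benefit"], y.mean(), atol=1e-12)

    def test_invalid_grid_rejected(self):
        y = np.repeat([0, 1], 10)
        with pytest.raises(InvalidParameterError):
            decision_curve(np.full(20, 0.5), y, thresholds=[0.5, 1.0])

    def test_invalid_probabilities_rejected(self):
        y = np.repeat([0, 1], 10)
        with pytest.raises(InvalidParameterError):
            decision_curve(np.linspace(0, 1, 20), y)


class TestEndToEnd:
    def test_task_runner_beats_chance_on_informative_cohort(self):
        coh = simulate_feature_cohort(CohortSpec(seed=21, feature_effect=1.5))
        res = run_subtype_task(coh.table, coh.labels, SplitSpec(seed=21))
        assert res.train_roc.auc > 0.9
        assert res.test_roc.auc > 0.8
        assert res.model.selected  # something was selected
        assert (res.test_dca["treat_none"] == 0).all()
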