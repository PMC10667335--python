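"""Classifiers, the repeated-split protocol, and the ancillary statistics."""

import itertools

import numpy as np
import pytest

from pdvoice.evaluate import (
    EvalProtocol,
    RepeatedSplitEvaluation,
    age_adjusted_group_test,
    auc,
    chi_square_independence,
    pairwise_correlations,
    run_protocol,
    train_logistic_aic,
    train_random_forest,
)
from pdvoice.exceptions import PdVoiceError, ProtocolError


def auc_pair_counting_oracle(scores, labels):
    """Exhaustive concordant-pair count over positive x negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def informative_design(seed, n=200, p=10):
    """One strongly informative column among pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, p))
    X[:, 3] += 2.5 * y
    return X, y


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ProtocolError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pair_counting_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert auc(scores, labels) == pytest.approx(
                auc_pair_counting_oracle(scores, labels), abs=1e-12
            )


class TestLogisticAic:
    def test_informative_feature_selected(self):
        hits = 0
        for seed in range(20):
            X, y = informative_design(seed)
            model = train_logistic_aic(X, y)
            hits += "x3" in model.selected
        assert hits >= 18

    def test_null_labels_allow_intercept_only_model(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.integers(0, 2, 100)
        model = train_logistic_aic(X, y)
        assert isinstance(model.selected, list)  # may legitimately be empty

    def test_selected_model_aic_not_worse_than_full_model(self):
        import statsmodels.api as sm

        X, y = informative_design(3, n=150, p=6)
        model = train_logistic_aic(X, y)
        full = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="bfgs", maxiter=200)
        assert model.aic <= full.aic + 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ProtocolError):
            train_logistic_aic(np.ones((4, 2)), [1, 1, 1, 1])


class TestRandomForest:
    def test_informative_feature_has_highest_gini_importance(self):
        hits = 0
        for seed in range(20):
            X, y = informative_design(seed, n=120)
            forest = train_random_forest(X, y, n_trees=200, rng_seed=seed)
            hits += int(np.argmax(forest.feature_importances_) == 3)
        assert hits >= 18

    def test_overfitting_visible_only_out_of_sample(self, rng):
        """On pure noise the forest memorizes training data but cannot
        generalize: train AUC near 1, held-out AUC near 1/2."""
        held_out = []
        train = np.r_[0:30, 40:70]
        test = np.r_[30:40, 70:80]
        y = np.repeat([0, 1], 40)
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((80, 10))
            forest = train_random_forest(X[train], y[train], n_trees=200, rng_seed=seed)
            train_auc = auc(forest.predict_proba(X[train])[:, 1], y[train])
            test_auc = auc(forest.predict_proba(X[test])[:, 1], y[test])
            assert train_auc >= 0.9
            held_out.append(test_auc)
        assert 0.35 <= np.mean(held_out) <= 0.65

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((60, 8))
        y = rng.integers(0, 2, 60)
        a = train_random_forest(X, y, n_trees=100, rng_seed=5)
        b = train_random_forest(X, y, n_trees=100, rng_seed=5)
        assert np.array_equal(a.feature_importances_, b.feature_importances_)

    def test_mtry_exceeding_feature_count_rejected(self, rng):
        with pytest.raises(ProtocolError):
            train_random_forest(rng.standard_normal((20, 4)), [0, 1] * 10, m_try=6)


class TestProtocol:
    def test_null_cohort_auc_near_half(self, rng):
        X = rng.standard_normal((80, 8))
        y = np.repeat([0, 1], 40)
        protocol = EvalProtocol(n_iterations=12, rng_seed=4, inner_cv=False)
        result = run_protocol(X, y, "rf", protocol, rf_kwargs={"n_trees": 200})
        assert 0.4 <= result.mean_auc <= 0.6

    def test_separable_cohort_auc_high(self, rng):
        X = rng.standard_normal((80, 8))
        y = np.repeat([0, 1], 40)
        X[:, 0] += 3.0 * y
        protocol = EvalProtocol(n_iterations=10, rng_seed=4, inner_cv=False)
        result = run_protocol(X, y, "rf", protocol, rf_kwargs={"n_trees": 200})
        assert result.mean_auc >= 0.9

    def test_identical_seed_identical_auc_vector(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.repeat([0, 1], 30)
        protocol = EvalProtocol(n_iterations=5, rng_seed=11, inner_cv=False)
        a = run_protocol(X, y, "rf", protocol, rf_kwargs={"n_trees": 100})
        b = run_protocol(X, y, "rf", protocol, rf_kwargs={"n_trees": 100})
        assert np.array_equal(a.auc_per_iteration, b.auc_per_iteration)

    def test_summary_table_shape(self, rng):
        X = rng.standard_normal((40, 4))
        y = np.repeat([0, 1], 20)
        result = run_protocol(
            X, y, "rf", EvalProtocol(n_iterations=3, rng_seed=0, inner_cv=False),
            rf_kwargs={"n_trees": 50},
        )
        table = result.summary()
        assert list(table.columns) == [
            "model", "iterations", "mean_auc", "sd_auc", "mean_cv_auc"
        ]
        assert result.auc_per_iteration.shape == (3,)


class TestAncillaryStatistics:
    def test_study_sex_by_group_table_is_independent(self):
        stat, p = chi_square_independence([[16, 24], [21, 19]])
        assert p > 0.05
        assert p == pytest.approx(0.2622, abs=1e-3)

    def test_proportional_table_statistic_zero(self):
        stat, p = chi_square_independence([[10, 10], [20, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_equals_brute_force_cell_sum(self):
        table = np.array([[16.0, 24.0], [21.0, 19.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        stat, _ = chi_square_independence(table)
        assert stat == pytest.approx(brute, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(PdVoiceError):
            chi_square_independence([[0, 0], [5, 3]])

    def test_group_effect_detected_with_age_adjustment(self):
        detected = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            group = np.repeat(["HC", "PD"], 40)
            age = r.normal(55, 10, 80)
            values = 2.0 * (group == "PD") + r.standard_normal(80)
            res = age_adjusted_group_test(values, group, age)
            detected += int(res.group_p < 0.05 and res.age_p >= 0.05)
        assert detected >= 90

    def test_null_feature_p_values_uniform(self):
        below = 0
        for seed in range(1000):
            r = np.random.default_rng(20_000 + seed)
            group = np.repeat(["HC", "PD"], 15)
            age = r.normal(55, 10, 30)
            values = r.standard_normal(30)
            below += int(age_adjusted_group_test(values, group, age).group_p < 0.05)
        assert 0.01 <= below / 1000 <= 0.10

    def test_age_shift_leaves_group_p_unchanged(self, rng):
        group = np.repeat(["HC", "PD"], 25)
        age = rng.normal(55, 12, 50)
        values = (group == "PD") + 0.03 * age + rng.standard_normal(50)
        a = age_adjusted_group_test(values, group, age)
        b = age_adjusted_group_test(values, group, age + 100.0)
        assert a.group_p == pytest.approx(b.group_p, abs=1e-8)

    def test_collinear_design_rejected(self):
        group = np.repeat(["HC", "PD"], 5)
        age = np.where(group == "PD", 70.0, 50.0)  # age fully determined by group
        with pytest.raises(PdVoiceError):
            age_adjusted_group_test(np.arange(10.0), group, age)

    def test_correlation_diagonal_and_antisymmetric_pair(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, -x, rng.standard_normal(50)])
        corr = pairwise_correlations(X)
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_column_flagged_not_propagated(self, rng):
        X = np.column_stack([rng.standard_normal(20), np.full(20, 3.0)])
        with pytest.warns(UserWarning):
            corr = pairwise_correlations(X)
        assert np.isnan(corr[0, 1]) and corr[0, 0] == pytest.approx(1.0)
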