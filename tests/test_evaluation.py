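"""Fold plans, AUC, LOOCV, ranking, permutation tests and Mann-Whitney U."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from cyspresso import evaluation as ev


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------


def balanced_flags(per_stratum):
    knottin = np.repeat([False, False, True, True], per_stratum)
    expressed = np.tile(np.repeat([False, True], per_stratum), 2)
    return knottin, expressed


class TestBalancedFolds:
    def test_one_record_per_stratum_per_fold(self):
        knottin, expressed = balanced_flags(10)
        plan = ev.make_balanced_folds(knottin, expressed, k=10, seed=0)
        for fold in range(10):
            idx = plan.fold_indices(fold)
            assert idx.size == 4
            assert sorted(plan.strata[idx]) == [0, 1, 2, 3]

    def test_two_records_per_stratum_per_fold(self):
        knottin, expressed = balanced_flags(4)
        plan = ev.make_balanced_folds(knottin, expressed, k=2, seed=1)
        for fold in range(2):
            counts = np.bincount(plan.strata[plan.fold_indices(fold)], minlength=4)
            assert np.all(counts == 2)

    def test_same_seed_gives_identical_plan(self):
        knottin, expressed = balanced_flags(7)
        a = ev.make_balanced_folds(knottin, expressed, k=5, seed=9)
        b = ev.make_balanced_folds(knottin, expressed, k=5, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_per_stratum_counts_differ_by_at_most_one_over_seed_sweep(self):
        rng = np.random.default_rng(0)
        knottin = rng.random(97) < 0.3
        expressed = rng.random(97) < 0.5
        for seed in range(100):
            plan = ev.make_balanced_folds(knottin, expressed, k=7, seed=seed)
            for cell in range(4):
                members = plan.assignment[plan.strata == cell]
                counts = np.bincount(members, minlength=7)
                assert counts.max() - counts.min() <= 1

    def test_small_stratum_warns_not_errors(self):
        knottin = np.array([False] * 20 + [True] * 2)
        expressed = np.array([True, False] * 11)
        with pytest.warns(UserWarning, match="folds will lack"):
            ev.make_balanced_folds(knottin, expressed, k=5, seed=0)


# ---------------------------------------------------------------------------
# AUC and confusion metrics
# ---------------------------------------------------------------------------


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        assert ev.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_scores_identical(self):
        assert ev.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_example(self):
        assert ev.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.2], [1, 1])

    def test_equals_brute_force_pair_counting_and_u_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = sum(
                1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
            )
            brute = pairs / (len(pos) * len(neg))
            auc = ev.roc_auc(scores, labels)
            assert auc == pytest.approx(brute, abs=1e-12)
            u = ev.mann_whitney_u(pos, neg).u
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        assert ev.roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 40))
    def test_antisymmetry_under_score_negation(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        labels = np.r_[0, 1, rng.integers(0, 2, size=n - 2)]
        assert ev.roc_auc(scores, labels) == pytest.approx(
            1.0 - ev.roc_auc(-scores, labels), abs=1e-12
        )


class TestConfusionMetrics:
    def test_all_correct_gives_ones(self):
        cm = ev.ConfusionMatrix(tp=10, fp=0, tn=10, fn=0)
        assert all(v == 1.0 for v in ev.metrics_from_confusion(cm).values())

    def test_degenerate_denominator_reported_absent(self):
        cm = ev.ConfusionMatrix(tp=0, fp=0, tn=10, fn=10)
        metrics = ev.metrics_from_confusion(cm)
        assert metrics["sensitivity"] == 0.0
        assert metrics["precision"] is None

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ev.metrics_from_confusion(ev.ConfusionMatrix(0, 0, 0, 0))

    def test_closed_forms(self):
        cm = ev.ConfusionMatrix(tp=6, fp=2, tn=8, fn=4)
        metrics = ev.metrics_from_confusion(cm)
        assert metrics["sensitivity"] == 0.6
        assert metrics["specificity"] == 0.8
        assert metrics["precision"] == 0.75
        assert metrics["accuracy"] == 0.7
        assert metrics["f1"] == pytest.approx(12 / 18)


# ---------------------------------------------------------------------------
# cross-validation and LOOCV
# ---------------------------------------------------------------------------


def oracle_trainer(y, noise=0.0, seed=0):
    """Injects scores equal to the true labels plus optional noise."""
    rng = np.random.default_rng(seed)

    def fn(train_idx, test_idx):
        return y[test_idx] + noise * rng.normal(size=test_idx.size)

    return fn


def random_trainer(seed=0):
    rng = np.random.default_rng(seed)

    def fn(train_idx, test_idx):
        return rng.random(test_idx.size)

    return fn


class TestCrossValidate:
    def test_perfect_oracle_scores_auc_one_every_fold(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=60)
        plan = ev.make_balanced_folds(np.zeros(60, bool), y.astype(bool), k=5, seed=0)
        result = ev.cross_validate(oracle_trainer(y), y, plan)
        assert result.fold_aucs == [1.0] * 5
        assert result.mean_auc == 1.0 and result.sd_auc == 0.0

    def test_out_of_fold_scores_cover_every_record(self):
        y = np.arange(40) % 2
        plan = ev.make_balanced_folds(np.zeros(40, bool), y.astype(bool), k=4, seed=0)
        result = ev.cross_validate(oracle_trainer(y), y, plan)
        assert not np.isnan(result.oof_scores).any()


class TestLoocv:
    def test_constant_score_model_gives_half_auc_one_class(self):
        y = np.arange(20) % 2

        def constant(train_idx, test_idx):
            return np.full(test_idx.size, 0.5)

        report = ev.loocv(constant, y)
        assert report.auc == 0.5
        assert report.confusion.tn == 0 and report.confusion.fn == 0  # all predicted 1

    def test_separable_toy_perfect(self):
        rng = np.random.default_rng(8)
        X = np.r_[rng.normal(-2, 0.2, size=(10, 1)), rng.normal(2, 0.2, size=(10, 1))]
        y = np.array([0] * 10 + [1] * 10)

        def nearest_mean(train_idx, test_idx):
            mu0 = X[train_idx][y[train_idx] == 0].mean()
            mu1 = X[train_idx][y[train_idx] == 1].mean()
            d = (X[test_idx, 0] - mu0) ** 2 - (X[test_idx, 0] - mu1) ** 2
            return 1.0 / (1.0 + np.exp(-d))

        report = ev.loocv(nearest_mean, y)
        assert report.auc == 1.0
        assert report.confusion.fp == 0 and report.confusion.fn == 0

    def test_equals_n_fold_cross_validation_with_singleton_folds(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=24)

        def trainer(train_idx, test_idx):
            # deterministic score: mean label of the k nearest train indices
            return np.array([y[train_idx].mean() + 0.01 * t for t in test_idx])

        report = ev.loocv(trainer, y)
        cv = ev.cross_validate(trainer, y, ev.singleton_folds(24))
        assert report.auc == ev.roc_auc(cv.oof_scores, y)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


class TestRankModels:
    def setup_method(self):
        rng = np.random.default_rng(10)
        self.y = rng.integers(0, 2, size=80)
        self.strata = self.y.copy()

    def test_duplicated_model_shares_ranks_and_group(self):
        models = {
            "a": oracle_trainer(self.y, noise=0.3, seed=1),
            "b": oracle_trainer(self.y, noise=0.3, seed=1),
        }
        result = ev.rank_models(models, self.y, self.strata, n_permutations=10, seed=0)
        assert result.mean_ranks[0] == pytest.approx(result.mean_ranks[1])
        assert result.same_group.all()

    def test_oracle_beats_random_model(self):
        models = {
            "oracle": oracle_trainer(self.y, noise=0.05, seed=2),
            "random": random_trainer(seed=3),
        }
        result = ev.rank_models(models, self.y, self.strata, n_permutations=20, seed=0)
        oracle_idx = result.model_names.index("oracle")
        assert result.mean_ranks[oracle_idx] == 1.0
        assert not result.same_group[0, 1]

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            ev.rank_models({"only": random_trainer()}, self.y, self.strata)

    def test_table_is_sorted_by_mean_rank(self):
        models = {
            "oracle": oracle_trainer(self.y, noise=0.05, seed=2),
            "random": random_trainer(seed=3),
        }
        result = ev.rank_models(models, self.y, self.strata, n_permutations=10, seed=0)
        table = result.to_table()
        assert table[0]["model"] == "oracle"
        assert table[0]["mean_rank"] <= table[1]["mean_rank"]


def test_nemenyi_critical_difference_matches_published_constant():
    # Nemenyi q_{0.05} for k=2 is 1.960 (studentized range / sqrt(2));
    # CD = q * sqrt(k(k+1)/(6N))
    cd = ev.nemenyi_critical_difference(2, 50, alpha=0.05)
    assert cd == pytest.approx(1.959964 * math.sqrt(6 / 300), rel=1e-4)
    # and the k=3 constant from the same published table
    cd3 = ev.nemenyi_critical_difference(3, 50, alpha=0.05)
    assert cd3 == pytest.approx(2.343701 * math.sqrt(12 / 300), rel=1e-4)


# ---------------------------------------------------------------------------
# permutation test on AUC
# ---------------------------------------------------------------------------


class TestPairedPermutation:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.y = rng.integers(0, 2, size=120)
        self.scores = rng.random(120)

    def test_identical_models_give_p_near_one(self):
        result = ev.paired_permutation_test_scores(
            self.scores, self.scores, self.y, n_iterations=1000, seed=0
        )
        assert result.p_value >= 0.9

    def test_two_tailed_symmetry_under_relabeling(self):
        other = np.random.default_rng(12).random(120)
        p_ab = ev.paired_permutation_test_scores(
            self.scores, other, self.y, n_iterations=2000, seed=0
        ).p_value
        p_ba = ev.paired_permutation_test_scores(
            other, self.scores, self.y, n_iterations=2000, seed=0
        ).p_value
        assert abs(p_ab - p_ba) < 0.05

    def test_oracle_vs_random_is_significant(self):
        oracle = self.y + 0.05 * np.random.default_rng(13).normal(size=120)
        result = ev.paired_permutation_test_scores(
            oracle, self.scores, self.y, n_iterations=2000, seed=0
        )
        assert result.p_value < 0.01

    def test_fold_unit_requires_folds(self):
        with pytest.raises(ValueError):
            ev.paired_permutation_test_scores(
                self.scores, self.scores, self.y, unit="fold"
            )

    def test_p_value_smoothing_never_zero(self):
        oracle = self.y.astype(float)
        result = ev.paired_permutation_test_scores(
            oracle, self.scores, self.y, n_iterations=500, seed=0
        )
        assert result.p_value >= 1 / 501


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_exact_p_is_one(self):
        result = ev.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.method == "exact"
        assert result.p_value == 1.0

    def test_fully_separated_small_samples(self):
        result = ev.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert result.u == 0.0
        assert result.method == "exact"
        assert result.p_value == pytest.approx(0.1)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 8)))
            b = rng.normal(size=int(rng.integers(3, 8)))
            ours = ev.mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.u == pytest.approx(float(ref.statistic))
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(15)
        a = np.round(rng.normal(size=40), 1)
        b = np.round(rng.normal(0.5, size=45), 1)
        ours = ev.mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.method == "asymptotic"
        assert ours.p_value == pytest.approx(float(ref.pvalue))

    @settings(deadline=None, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        na=st.integers(2, 6),
        nb=st.integers(2, 6),
    )
    def test_u_statistics_of_both_samples_sum_to_product(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(size=na), 1)
        b = np.round(rng.normal(size=nb), 1)
        u_a = ev.mann_whitney_u(a, b).u
        u_b = ev.mann_whitney_u(b, a).u
        assert u_a + u_b == pytest.approx(na * nb)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.mann_whitney_u([], [1.0])
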