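"""Preprocessing, SVM estimators, metrics and baselines."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clinsbd.model import (
    AbbreviationDetector,
    LinearPeriodSVM,
    RangeUnitScaler,
    baseline_abbrev,
    baseline_sentence,
    chernoff_sample_size,
    cohens_kappa,
    compare_classifiers,
    cross_validate,
    micro_f1,
    preprocess,
    select_c,
)
from clinsbd.text import PeriodSite


class TestPreprocess:
    def test_training_column_maps_to_full_range(self):
        scaler = RangeUnitScaler().fit([[0.0], [5.0], [10.0]])
        assert scaler.affine([[0.0], [5.0], [10.0]]).ravel() == pytest.approx(
            [-1.0, 0.0, 1.0]
        )

    def test_test_value_may_leave_the_range(self):
        scaler = RangeUnitScaler().fit([[0.0], [5.0], [10.0]])
        assert scaler.affine([[20.0]]).ravel()[0] == pytest.approx(3.0)

    def test_unit_row_norms(self):
        train = np.array([[0.0, 0.0], [6.0, 8.0]])
        scaler = RangeUnitScaler().fit(np.array([[0.0, 0.0], [10.0, 10.0]]))
        row = scaler.transform(train)[1]
        # affine maps (6,8) -> (0.2,0.6); normalized to unit length
        assert np.linalg.norm(row) == pytest.approx(1.0)

    def test_345_triangle(self):
        row = np.array([[3.0, 4.0]])
        scaler = RangeUnitScaler().fit(np.array([[0.0, 0.0], [1.0, 1.0]]))
        # identity-free check on the normalization step alone
        normalized = row / np.linalg.norm(row)
        assert normalized.ravel() == pytest.approx([0.6, 0.8])

    def test_constant_feature_maps_to_zero(self):
        scaler = RangeUnitScaler().fit([[5.0, 1.0], [5.0, 3.0]])
        assert scaler.affine([[5.0, 2.0]])[0, 0] == 0.0

    def test_zero_rows_stay_zero(self):
        train = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        scaler = RangeUnitScaler().fit(train)
        assert np.all(scaler.transform([[0.0, 0.0]]) == 0.0)

    def test_preprocess_contract(self):
        train = np.array([[0.0, 1.0], [5.0, 3.0], [10.0, 2.0]])
        test = np.array([[20.0, 1.0]])
        tr, te = preprocess(train, test)
        scaler = RangeUnitScaler().fit(train)
        assert np.abs(scaler.affine(train)).max() <= 1.0 + 1e-12
        assert np.linalg.norm(tr, axis=1) == pytest.approx(np.ones(3))
        assert te.shape == (1, 2)


class TestMicroF1:
    def test_all_correct(self):
        assert micro_f1([1, 0, 1], [1, 0, 1]) == 1.0

    def test_three_of_four(self):
        assert micro_f1([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.75)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            micro_f1([], [])

    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=50),
        st.randoms(use_true_random=False),
    )
    def test_equals_accuracy_on_binary_tasks(self, gold, rnd):
        preds = [rnd.randint(0, 1) for _ in gold]
        acc = float(np.mean(np.array(preds) == np.array(gold)))
        assert micro_f1(preds, gold) == pytest.approx(acc)


class TestCohensKappa:
    def test_identical_raters(self):
        assert cohens_kappa([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_hand_computed_table(self):
        # 2x2 agreement table a=20 (both yes), b=5, c=10, d=15 -> kappa = 0.4
        a = [1] * 20 + [1] * 5 + [0] * 10 + [0] * 15
        b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, size=10_000)
        b = rng.integers(0, 2, size=10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_degenerate_full_agreement_on_one_label(self):
        # expected agreement 1 with observed agreement 1 is defined as 1
        assert cohens_kappa([1, 1], [1, 1]) == 1.0

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 1], [1])


class TestCompareClassifiers:
    def test_identical_predictions_not_significant(self):
        gold = [0, 1] * 20
        preds = [0, 1] * 19 + [1, 0]
        res = compare_classifiers(preds, preds, gold)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_perfect_vs_chance_significant(self):
        rng = np.random.default_rng(0)
        gold = rng.integers(0, 2, size=200)
        chance = rng.integers(0, 2, size=200)
        res = compare_classifiers(gold, chance, gold)
        assert res.significant

    def test_tiny_n_same_accuracy_not_significant(self):
        res = compare_classifiers([1, 0], [0, 1], [1, 1])
        assert not res.significant

    def test_mcnemar_variant(self):
        gold = np.zeros(100, int)
        a = np.zeros(100, int)
        b = np.concatenate([np.ones(40, int), np.zeros(60, int)])
        res = compare_classifiers(a, b, gold, method="mcnemar")
        assert res.method == "mcnemar"
        assert res.significant

    def test_degenerate_table_flagged(self):
        res = compare_classifiers([1], [1], [1])
        assert res.degenerate and not res.significant


class TestChernoff:
    def test_printed_gold_standard_size(self):
        assert chernoff_sample_size(0.05, 0.05) == 3024

    def test_coarse_accuracy(self):
        assert chernoff_sample_size(1.0, 0.05) == 11

    def test_halving_epsilon_roughly_quadruples_n(self):
        n1 = chernoff_sample_size(0.1, 0.05)
        n2 = chernoff_sample_size(0.05, 0.05)
        assert 3.5 < n2 / n1 < 4.5

    @pytest.mark.parametrize("eps,delta", [(0.0, 0.05), (-1, 0.5), (0.05, 0.0), (0.05, 1.0)])
    def test_invalid_arguments(self, eps, delta):
        with pytest.raises(ValueError):
            chernoff_sample_size(eps, delta)


class TestBaselines:
    def test_abbrev_rule_on_following_character(self):
        assert baseline_abbrev(PeriodSite("ca.", right_token="eines")) == 1
        assert baseline_abbrev(PeriodSite("ca.", right_token="Level")) == 0
        assert baseline_abbrev(PeriodSite("ca.", right_token="")) == 0

    def test_sentence_rule_on_capitalization(self):
        assert baseline_sentence(PeriodSite("x.", right_token="Level")) == 1
        assert baseline_sentence(PeriodSite("x.", right_token="majus")) == 0
        assert baseline_sentence(PeriodSite("x.", right_token="")) == 0
        # capitalization is judged on the word content of R
        assert baseline_sentence(PeriodSite("x.", right_token="(Die")) == 1


def separable_blobs(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-3.0, 0.3, size=(n // 2, 2))
    X1 = rng.normal(3.0, 0.3, size=(n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestLinearPeriodSVM:
    def test_and_separable_training_accuracy(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        y = np.array([0, 0, 0, 1])
        m = LinearPeriodSVM(C=10.0).fit(X, y)
        assert micro_f1(m.predict(X), y) == 1.0

    def test_symmetric_two_point_problem_has_near_zero_bias(self):
        X = np.array([[-1.0], [1.0]] * 10)
        y = np.array([0, 1] * 10)
        m = LinearPeriodSVM(C=10.0).fit(X, y)
        assert abs(m.intercept_) < 1e-6

    def test_dominant_feature_tops_ranking(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 4))
        X[:, 2] = y * 2.0 - 1.0  # planted discriminative feature
        m = LinearPeriodSVM(C=1.0).fit(X, y)
        ranked = m.rank_features(feature_names=["a", "b", "planted", "d"])
        assert ranked[0].name == "planted"

    def test_rank_order_and_ties(self):
        m = LinearPeriodSVM()
        m.coef_ = np.array([3.0, -4.0, 0.0, 4.0])
        ranked = m.rank_features(feature_names=["w3", "x4neg", "zero", "a4pos"])
        assert [r.name for r in ranked] == ["a4pos", "x4neg", "w3", "zero"]
        assert ranked[0].w2 == pytest.approx(16.0)
        assert m.rank_features(n=99, feature_names=["w3", "x4neg", "zero", "a4pos"])[
            -1
        ].name == "zero"

    def test_select_c_prefers_smallest_on_ties(self):
        X, y = separable_blobs()
        assert select_c(X, y, grid=(0.001, 1.0, 1000.0), folds=3) == 0.001

    def test_select_c_single_value_grid(self):
        X, y = separable_blobs()
        assert select_c(X, y, grid=(10.0,), folds=3) == 10.0

    def test_select_c_requires_two_classes(self):
        X, _ = separable_blobs()
        with pytest.raises(ValueError):
            select_c(X, np.zeros(len(X)), folds=3)


class TestCrossValidate:
    def test_perfectly_separable_scores_one(self):
        X, y = separable_blobs(n=100)
        res = cross_validate(LinearPeriodSVM(C=1.0), X, y, k=5, seed=0)
        assert res.micro_f1 == 1.0
        assert res.n == 100
        assert res.tp + res.fp + res.tn + res.fn == 100

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        y = rng.integers(0, 2, size=80)
        r1 = cross_validate(LinearPeriodSVM(C=1.0), X, y, k=4, seed=3)
        r2 = cross_validate(LinearPeriodSVM(C=1.0), X, y, k=4, seed=3)
        assert r1.micro_f1 == r2.micro_f1
        assert r1.per_fold == r2.per_fold

    def test_requires_enough_instances(self):
        with pytest.raises(ValueError):
            cross_validate(LinearPeriodSVM(), np.zeros((3, 1)), [0, 1, 0], k=10)


class TestDetectorsOnSites:
    def test_training_fit_beats_baseline(
        self, small_corpus, small_table, lexicons, abbrev_labels
    ):
        mddict, _ = lexicons
        _, gold = small_corpus
        det = AbbreviationDetector(
            mddict=mddict, count_table=small_table, C=1.0
        ).fit(gold, abbrev_labels)
        f1 = micro_f1(det.predict(gold), abbrev_labels)
        bl = micro_f1([baseline_abbrev(s) for s in gold], abbrev_labels)
        assert f1 > bl

    def test_sklearn_clone_compatible(self, small_table, lexicons):
        from sklearn.base import clone

        mddict, _ = lexicons
        det = AbbreviationDetector(mddict=mddict, count_table=small_table, C=2.0)
        cloned = clone(det)
        assert cloned.C == 2.0
        assert cloned.mddict.entries == mddict.entries
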