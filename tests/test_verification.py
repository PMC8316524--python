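"""Pair building, classifiers, cross-validation, ROC/EER, uniqueness."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaituniq.simulate import generate_feature_cohort
from gaituniq.verification import (
    PairCase,
    VerificationError,
    build_pair_dataset,
    count_diff_pairs,
    cross_validate,
    enumerate_same_pairs,
    norm_score,
    roc_and_eer,
    sample_diff_pairs,
    train_pair_classifier,
    uniqueness_estimates,
)

from conftest import eer_oracle, random_score_set


def separable_dataset(seed=0, n_subjects=20):
    """sigma_b >> sigma_w: same-pairs near zero, diff-pairs far."""
    X, lab = generate_feature_cohort(n_subjects, 4, 4, np.full(4, 5.0),
                                     np.full(4, 0.05), seed=seed)
    return build_pair_dataset(X, lab, seed=seed + 1)


class TestPairCase:
    def test_abs_difference(self):
        c = PairCase(np.array([-1.0, 2.0]), False, ("a", "b"))
        np.testing.assert_array_equal(c.abs_difference, [1.0, 2.0])

    def test_label_subject_consistency_enforced(self):
        with pytest.raises(VerificationError):
            PairCase(np.zeros(2), True, ("a", "b"))


class TestPairCounts:
    def test_small_example(self):
        X = np.arange(8.0).reshape(4, 2)
        labels = ["a", "a", "b", "b"]
        same = enumerate_same_pairs(X, labels)
        assert len(same) == 2
        assert all(c.label for c in same)
        assert count_diff_pairs(labels) == 4

    def test_single_observation_contributes_nothing(self):
        X = np.zeros((3, 2))
        assert len(enumerate_same_pairs(X, ["a", "b", "b"])) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=2, max_size=8))
    def test_closed_forms_match_brute_force(self, sizes):
        labels = [f"s{i}" for i, n in enumerate(sizes) for _ in range(n)]
        X = np.zeros((len(labels), 1))
        n_same_expected = sum(n * (n - 1) // 2 for n in sizes)
        brute_diff = sum(1 for i in range(len(labels))
                         for j in range(i + 1, len(labels))
                         if labels[i] != labels[j])
        assert len(enumerate_same_pairs(X, labels)) == n_same_expected
        assert count_diff_pairs(labels) == brute_diff

    def test_sample_full_population_is_enumeration(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 2))
        labels = ["a", "a", "b", "b", "c", "c"]
        total = count_diff_pairs(labels)
        cases = sample_diff_pairs(X, labels, total, seed=3)
        assert len(cases) == total
        keys = {tuple(np.round(c.difference, 9)) for c in cases}
        assert len(keys) == total

    def test_oversampling_rejected(self):
        X = np.zeros((4, 1))
        with pytest.raises(VerificationError):
            sample_diff_pairs(X, ["a", "a", "b", "b"], 5, seed=0)

    def test_sampling_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        labels = np.repeat([f"s{i}" for i in range(10)], 4)
        c1 = sample_diff_pairs(X, labels, 50, seed=9)
        c2 = sample_diff_pairs(X, labels, 50, seed=9)
        assert all(np.array_equal(a.difference, b.difference)
                   for a, b in zip(c1, c2))


class TestNormScore:
    def test_three_four_five(self):
        c = PairCase(np.array([3.0, -4.0]), False, ("a", "b"))
        assert norm_score(c, 1) == 7.0
        assert norm_score(c, 2) == 5.0
        assert norm_score(PairCase(np.zeros(3), True, ("a", "a")), 2) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
    def test_l2_never_exceeds_l1(self, diff):
        c = PairCase(np.array(diff), False, ("a", "b"))
        assert norm_score(c, 2) <= norm_score(c, 1) + 1e-12


def toy_separable_pairs(seed=0, n_per_class=40, k=4):
    """Constructed separable set: same-diffs in a tiny ball, diff-diffs far out."""
    from gaituniq.verification import PairDataset
    rng = np.random.default_rng(seed)
    same = rng.normal(0.0, 0.02, size=(n_per_class, k))
    directions = rng.standard_normal((n_per_class, k))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    diff = directions * rng.uniform(8.0, 12.0, size=(n_per_class, 1))
    ids_same = np.array([("a", "a")] * n_per_class)
    ids_diff = np.array([("a", "b")] * n_per_class)
    return PairDataset(np.vstack([same, diff]),
                       np.array([True] * n_per_class + [False] * n_per_class),
                       np.vstack([ids_same, ids_diff]))


class TestPairClassifier:
    @pytest.mark.parametrize("kernel", ["linear", "poly", "rbf"])
    def test_separable_training_accuracy(self, kernel):
        ds = toy_separable_pairs()
        clf = train_pair_classifier(ds, kernel)
        assert np.mean(clf.predict(ds.differences) == ds.labels) == 1.0

    def test_rbf_symmetric_under_negation(self):
        ds = separable_dataset(seed=2)
        clf = train_pair_classifier(ds, "rbf", symmetrize=True)
        d1 = clf.decision(ds.differences)
        d2 = clf.decision(-ds.differences)
        # decision function is unique at convergence; allow solver tolerance
        np.testing.assert_allclose(d1, d2, atol=1e-4)
        np.testing.assert_array_equal(d1 > 0, d2 > 0)

    def test_zero_difference_on_same_side(self):
        ds = separable_dataset(seed=3)
        for kernel in ("linear", "poly", "rbf"):
            clf = train_pair_classifier(ds, kernel)
            assert clf.decision(np.zeros((1, 4)))[0] > 0

    def test_single_class_rejected(self):
        X, lab = generate_feature_cohort(5, 4, 2, np.ones(2), np.ones(2), seed=0)
        same = enumerate_same_pairs(X, lab)
        from gaituniq.verification import PairDataset
        ds = PairDataset(np.array([c.difference for c in same]),
                         np.array([c.label for c in same]),
                         np.array([c.subject_ids for c in same]))
        with pytest.raises(VerificationError, match="both classes"):
            train_pair_classifier(ds, "linear")


class TestCrossValidate:
    def test_folds_partition_cases(self):
        ds = separable_dataset(seed=4)
        res = cross_validate(ds, "l2", folds=5, seed=0)
        counts = np.bincount(res.fold_assignment, minlength=5)
        assert counts.sum() == len(ds)
        assert counts.min() >= 1

    def test_well_separated_cohort_near_perfect(self):
        res = cross_validate(separable_dataset(seed=5), "l2", seed=1)
        assert res.accuracy > 0.99

    def test_permuted_labels_at_chance(self):
        X, lab = generate_feature_cohort(40, 4, 4, np.full(4, 5.0),
                                         np.full(4, 0.05), seed=6)
        ds = build_pair_dataset(X, lab, seed=7)
        rng = np.random.default_rng(8)
        ds.labels = rng.permutation(ds.labels)
        # labels no longer match subject ids, but scores only use labels
        res = cross_validate(ds, "l2", seed=9)
        se = 0.5 / np.sqrt(len(ds))
        assert abs(res.accuracy - 0.5) <= 3 * se

    def test_accuracy_invariant_to_pair_order_swap(self):
        ds = separable_dataset(seed=10)
        res1 = cross_validate(ds, "l1", seed=2)
        ds.differences = -ds.differences
        res2 = cross_validate(ds, "l1", seed=2)
        assert res1.accuracy == res2.accuracy
        assert res1.eer == res2.eer

    def test_too_many_folds_rejected(self):
        ds = separable_dataset(seed=11)
        with pytest.raises(VerificationError):
            cross_validate(ds, "l2", folds=len(ds) + 1)

    def test_l1_accuracy_at_eer_threshold(self):
        """On balanced data 1 - accuracy at the EER point equals the EER."""
        X, lab = generate_feature_cohort(30, 4, 4, np.full(4, 1.5),
                                         np.full(4, 1.0), seed=12)
        ds = build_pair_dataset(X, lab, seed=13)
        res = cross_validate(ds, "l1", seed=14)
        k = int(np.argmin(np.abs(res.far_curve - res.frr_curve)))
        acc_at_eer = 1.0 - 0.5 * (res.far_curve[k] + res.frr_curve[k])
        assert abs((1.0 - acc_at_eer) - res.eer) <= 1.0 / ds.n_same + 1e-12


class TestRocAndEer:
    def test_perfect_separation(self):
        scores = np.array([3.0, 2.5, -1.0, -2.0])
        labels = np.array([True, True, False, False])
        *_, eer = roc_and_eer(scores, labels)
        assert eer == 0.0

    def test_all_identical_scores(self):
        scores = np.ones(10)
        labels = np.array([True] * 5 + [False] * 5)
        *_, eer = roc_and_eer(scores, labels)
        assert eer == pytest.approx(0.5)

    def test_curves_monotone(self):
        rng = np.random.default_rng(15)
        scores, labels = random_score_set(rng)
        _, far, frr, _ = roc_and_eer(scores, labels)
        assert np.all(np.diff(far) >= 0)    # looser threshold -> more accepts
        assert np.all(np.diff(frr) <= 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        scores, labels = random_score_set(np.random.default_rng(seed))
        *_, eer = roc_and_eer(scores, labels)
        assert abs(eer - eer_oracle(scores, labels)) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(VerificationError):
            roc_and_eer(np.ones(4), np.ones(4, dtype=bool))


class TestUniqueness:
    def test_reported_population_arithmetic(self):
        bound, special, general = uniqueness_estimates(0.0027, 10)
        assert bound == pytest.approx(0.027)
        assert special == pytest.approx(0.973)
        assert general == pytest.approx(0.761, abs=5e-4)

    def test_zero_eer(self):
        assert uniqueness_estimates(0.0, 10) == (0.0, 1.0, 1.0)

    def test_population_one_general_equals_special(self):
        bound, special, general = uniqueness_estimates(0.1, 1)
        assert general == special == 0.9

    def test_degenerate_bound_rejected(self):
        with pytest.raises(VerificationError):
            uniqueness_estimates(0.2, 10)
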