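"""Fold bookkeeping, confusion/kappa arithmetic (vs sklearn oracle) and
method-comparison statistics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import fexbci
from fexbci.evaluate import (compare_methods, confusion_matrix,
                             cross_validate, make_folds, metrics)


class TestFolds:
    def test_240_epochs_split_192_48(self):
        labels = np.repeat(np.arange(4), 60)
        plan = make_folds(240, labels, k=5, seed=0)
        for tr, te in plan.folds():
            assert len(tr) == 192 and len(te) == 48
            # stratified: every class in every training fold and test fold
            assert len(np.unique(labels[tr])) == 4
            assert len(np.unique(labels[te])) == 4

    def test_folds_partition_the_indices(self):
        labels = np.repeat(np.arange(4), 10)
        plan = make_folds(40, labels, k=5, repeats=2, seed=3)
        for r in range(2):
            seen = [te for _, te in plan.folds(r)]
            all_idx = np.sort(np.concatenate(seen))
            assert np.array_equal(all_idx, np.arange(40))
            for i in range(5):
                for j in range(i + 1, 5):
                    assert len(np.intersect1d(seen[i], seen[j])) == 0

    def test_ten_epochs_five_folds_of_two(self):
        labels = np.tile([0, 1], 5)
        plan = make_folds(10, labels, k=5, seed=1)
        assert all(len(te) == 2 for _, te in plan.folds())

    def test_thin_class_rejected(self):
        labels = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than k"):
            make_folds(13, labels, k=5)

    def test_deterministic_under_seed(self):
        labels = np.repeat(np.arange(4), 10)
        p1 = make_folds(40, labels, k=5, seed=9)
        p2 = make_folds(40, labels, k=5, seed=9)
        assert np.array_equal(p1.assignments, p2.assignments)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(4), 5)
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([5, 5, 5, 5]))

    def test_single_off_diagonal_count(self):
        cm = confusion_matrix([2], [3])
        expected = np.zeros((4, 4), dtype=int)
        expected[2, 3] = 1
        assert np.array_equal(cm, expected)

    def test_matches_bruteforce_tally(self, rng):
        yt = rng.integers(0, 4, 200)
        yp = rng.integers(0, 4, 200)
        cm = confusion_matrix(yt, yp)
        brute = np.zeros((4, 4), dtype=int)
        for a, b in zip(yt, yp):
            brute[a, b] += 1
        assert np.array_equal(cm, brute)

    def test_label_validation(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 4], [0, 0])
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([0, 1], [0])


class TestMetrics:
    def test_two_class_hand_computation(self):
        # TP=40, FN=10, FP=10, TN=40: p0=0.8, pe=0.5, kappa=0.6
        cm = np.array([[40, 10], [10, 40]])
        rep = metrics(cm)
        assert rep.p0 == pytest.approx(0.8)
        assert rep.pe == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(0.6)

    def test_diagonal_matrix_gives_kappa_one(self):
        rep = metrics(np.diag([10, 20, 30, 40]))
        assert rep.p0 == 1.0 and rep.kappa == pytest.approx(1.0)

    def test_independent_predictions_give_kappa_zero(self):
        # every row identical -> p0 == pe by construction
        row = np.array([10, 20, 30, 40])
        rep = metrics(np.tile(row, (4, 1)))
        assert rep.kappa == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_sklearn_oracle_on_random_matrices(self, rng):
        for _ in range(300):
            cm = rng.integers(0, 30, (4, 4))
            if cm.sum() == 0 or np.trace(cm) == cm.sum():
                continue
            yt = np.repeat(np.arange(4), cm.sum(axis=1))
            yp = np.concatenate([np.repeat(np.arange(4), cm[i])
                                 for i in range(4)])
            rep = metrics(cm)
            ref = cohen_kappa_score(yt, yp)
            assert rep.kappa == pytest.approx(ref, abs=1e-12)

    def test_kappa_invariant_under_class_permutation(self, rng):
        cm = rng.integers(0, 50, (4, 4))
        perm = rng.permutation(4)
        assert metrics(cm).kappa == pytest.approx(
            metrics(cm[np.ix_(perm, perm)]).kappa, abs=1e-12)

    def test_degenerate_pe_one_reported_as_undefined(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0] = 10
        rep = metrics(cm)
        assert rep.kappa is None and "pe = 1" in rep.kappa_undefined_reason


class TestCrossValidate:
    @staticmethod
    def _majority_fit_predict(train, test, fold_seed):
        vals, counts = np.unique(train.labels, return_counts=True)
        return np.full(test.n_epochs, vals[counts.argmax()])

    def test_pooled_p0_is_weighted_mean_of_fold_accuracies(self, small_epochs):
        plan = make_folds(small_epochs.n_epochs, small_epochs.labels, k=5,
                          seed=0)
        rep = cross_validate(small_epochs, plan, self._majority_fit_predict)
        sizes = [cm.sum() for cm in rep.fold_confusions]
        weighted = np.average(rep.fold_accuracies, weights=sizes)
        assert rep.p0 == pytest.approx(weighted)

    def test_fold_scoring_sizes(self, small_epochs):
        plan = make_folds(small_epochs.n_epochs, small_epochs.labels, k=5,
                          repeats=2, seed=0)
        rep = cross_validate(small_epochs, plan, self._majority_fit_predict)
        assert len(rep.fold_accuracies) == 10
        assert all(cm.sum() == 8 for cm in rep.fold_confusions)

    def test_deterministic_with_seeded_worker(self, small_epochs):
        seen = []

        def fp(train, test, fold_seed):
            rng = np.random.default_rng(fold_seed)
            return rng.integers(0, 4, test.n_epochs)

        plan = make_folds(small_epochs.n_epochs, small_epochs.labels, k=5,
                          seed=4)
        r1 = cross_validate(small_epochs, plan, fp)
        r2 = cross_validate(small_epochs, plan, fp)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)


class TestCompareMethods:
    def test_identical_vectors_give_t_zero_p_one(self):
        a = np.array([0.8, 0.85, 0.9, 0.8, 0.82])
        df = compare_methods({"m1": a, "m2": a.copy()})
        row = df[df.test == "paired_t"].iloc[0]
        assert row.statistic == 0.0 and row.p_value == 1.0

    def test_paired_t_matches_hand_computation(self):
        a = np.array([0.9, 0.8, 0.85, 0.95])
        b = np.array([0.7, 0.75, 0.8, 0.85])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        df = compare_methods({"a": a, "b": b})
        row = df[df.test == "paired_t"].iloc[0]
        assert row.statistic == pytest.approx(t_hand)

    def test_three_identical_groups_give_f_zero(self):
        a = np.array([0.8, 0.85, 0.9])
        df = compare_methods({"x": a, "y": a.copy(), "z": a.copy()})
        row = df[df.test == "anova"].iloc[0]
        assert row.statistic == pytest.approx(0.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            compare_methods({"a": [0.8, 0.9], "b": [0.8]})
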