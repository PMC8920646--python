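"""Forward selection, classifiers, validation schemes and metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score

from qustc.classifiers import MahalanobisKNN, make_classifier, predict_scores
from qustc.metrics import compute_metrics, cross_validate, rank_sum_screen
from qustc.selection import SequentialForwardSelector, SFSTrace


def separable_toy(rng, n=60, p=3, informative=1):
    X = rng.standard_normal((n, p))
    y = (rng.uniform(size=n) < 0.5).astype(int)
    X[:, informative] = y * 10.0 + rng.normal(scale=0.1, size=n)
    return X, y


class TestSequentialForwardSelection:
    def test_perfect_feature_selected_first_then_stop(self, rng):
        X, y = separable_toy(rng)
        sel = SequentialForwardSelector(MahalanobisKNN(), random_state=0).fit(X, y)
        assert sel.selected_idx_ == [1]
        assert sel.trace_.criteria == [0.0]

    def test_matches_brute_force_greedy_oracle(self, rng):
        X = rng.standard_normal((80, 3))
        y = (X[:, 0] + 0.8 * X[:, 2] + 0.5 * rng.standard_normal(80) > 0).astype(int)
        est = MahalanobisKNN()
        sel = SequentialForwardSelector(est, cv=10, random_state=0).fit(X, y)

        def crit(cols):
            cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
            return 1.0 - cross_val_score(MahalanobisKNN(), X[:, cols], y, cv=cv).mean()

        # independent greedy re-run
        remaining, chosen, best = [0, 1, 2], [], np.inf
        while remaining:
            scores = [crit(chosen + [c]) for c in remaining]
            i = int(np.argmin(scores))
            if scores[i] < best:
                best = scores[i]
                chosen.append(remaining.pop(i))
            else:
                break
        assert sel.selected_idx_ == chosen

    def test_criterion_strictly_decreasing_invariant(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.standard_normal((60, 6))
            y = (X[:, 0] + r.standard_normal(60) > 0).astype(int)
            sel = SequentialForwardSelector(
                make_classifier("random_forest", seed=0, n_estimators=25),
                random_state=seed,
            ).fit(X, y)
            assert all(
                b < a for a, b in zip(sel.trace_.criteria, sel.trace_.criteria[1:])
            )

    def test_pure_noise_short_trace(self):
        stops = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 5))
            y = r.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            sel = SequentialForwardSelector(MahalanobisKNN(), random_state=seed).fit(X, y)
            stops += len(sel.selected_idx_) <= 2
        assert stops >= 0.9 * 30

    def test_trace_invariants_enforced(self):
        with pytest.raises(ValueError, match="decreasing"):
            SFSTrace(selected=[0, 1], selected_names=["a", "b"], criteria=[0.2, 0.3])
        with pytest.raises(ValueError, match="unique"):
            SFSTrace(selected=[0, 0], selected_names=["a", "a"], criteria=[0.3, 0.2])

    def test_degenerate_labels_error(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="single class"):
            SequentialForwardSelector(MahalanobisKNN()).fit(X, np.zeros(20, dtype=int))


class TestClassifiers:
    def test_knn_vote_fraction_score(self, rng):
        # 5-NN with 4 of 5 malignant neighbors scores 0.8 and predicts 1
        X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [10.0]])
        y = np.array([1, 1, 1, 1, 0, 0])
        model = MahalanobisKNN(n_neighbors=5).fit(X, y)
        test = np.array([[0.15]])
        assert predict_scores(model, test)[0] == pytest.approx(0.8)
        assert model.predict(test)[0] == 1

    def test_knn_training_accuracy_on_separable(self, rng):
        X, y = separable_toy(rng, n=40)
        model = MahalanobisKNN().fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_forest_deterministic_under_seed(self, rng):
        X, y = separable_toy(rng, n=50)
        a = make_classifier("random_forest", seed=3).fit(X, y).predict(X)
        b = make_classifier("random_forest", seed=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_svm_scores_orientation(self, rng):
        X, y = separable_toy(rng, n=50)
        model = make_classifier("svm_linear").fit(X, y)
        s = predict_scores(model, X)
        assert s[y == 1].min() > s[y == 0].max()

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            MahalanobisKNN(n_neighbors=4).fit(np.zeros((6, 2)), np.array([0, 1] * 3))


class TestComputeMetrics:
    def test_confusion_hand_arithmetic(self):
        # TP=19 FN=1 TN=18 FP=2 -> sens 95, spec 90, acc 92.5
        y = np.array([1] * 20 + [0] * 20)
        pred = np.array([1] * 19 + [0] + [0] * 18 + [1] * 2)
        scores = pred + np.linspace(0, 0.1, 40)
        rep = compute_metrics(y, scores, pred, n_boot=50)
        assert rep.sensitivity == pytest.approx(95.0)
        assert rep.specificity == pytest.approx(90.0)
        assert rep.accuracy == pytest.approx(92.5)

    def test_score_reversal_flips_auc(self, rng):
        y = rng.integers(0, 2, 200)
        y[:5], y[-5:] = 0, 1
        s = rng.standard_normal(200) + y
        a = compute_metrics(y, s, n_boot=50).auc
        b = compute_metrics(y, -s, n_boot=50).auc
        assert a + b == pytest.approx(1.0)

    def test_auc_equals_mann_whitney_u(self, rng):
        import scipy.stats

        y = np.array([0] * 30 + [1] * 25)
        s = rng.standard_normal(55)  # ties-free with probability 1
        rep = compute_metrics(y, s, n_boot=50)
        u = scipy.stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided")
        assert rep.auc == pytest.approx(u.statistic / (30 * 25))

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics(np.ones(10), np.arange(10.0))


class TestCrossValidate:
    def test_perfectly_separated_scores(self, rng):
        X, y = separable_toy(rng, n=60, p=2, informative=0)
        rep = cross_validate(X, y, MahalanobisKNN(), scheme="kfold", seed=0, n_boot=50)
        assert rep.auc == 1.0
        assert rep.accuracy == 100.0

    def test_null_scores_auc_near_half(self):
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 4))
            y = np.array([0, 1] * 100)
            rep = cross_validate(
                X, y, make_classifier("random_forest", seed=seed),
                scheme="kfold", seed=seed, n_boot=50,
            )
            aucs.append(rep.auc)
        assert 0.4 < np.median(aucs) < 0.6

    def test_loocv_runs_n_fits(self, rng):
        X, y = separable_toy(rng, n=24, p=2)
        rep = cross_validate(X, y, MahalanobisKNN(), scheme="loocv", seed=0, n_boot=50)
        assert rep.n_fits == 24

    def test_holdout_uses_test_split_only(self, rng):
        X, y = separable_toy(rng, n=50, p=2)
        rep = cross_validate(X, y, MahalanobisKNN(), scheme="holdout", seed=0, n_boot=50)
        assert rep.tp + rep.fn + rep.tn + rep.fp == 20  # 40% of 50
        assert rep.n_fits == 1

    def test_kfold_requires_enough_members(self):
        X = np.zeros((30, 2))
        y = np.array([0] * 25 + [1] * 5)
        with pytest.raises(ValueError, match="10-fold"):
            cross_validate(X, y, MahalanobisKNN(), scheme="kfold")

    def test_auc_invariant_to_monotone_transform(self, rng):
        # scores pooled over folds: any strictly increasing transform of the
        # classifier score leaves the ROC/AUC unchanged by construction
        y = np.array([0] * 40 + [1] * 40)
        s = rng.standard_normal(80) + 0.8 * y
        a = compute_metrics(y, s, n_boot=50).auc
        b = compute_metrics(y, np.exp(3 * s), n_boot=50).auc
        assert a == pytest.approx(b)


class TestRankSumScreen:
    def test_identical_groups_not_significant(self):
        g = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        out = rank_sum_screen(g, g.copy())
        assert out.loc["f", "tier"] == "~"

    def test_exact_enumeration_small_groups(self):
        # {1,2,3} vs {10,11,12}: the most extreme split out of C(6,3)=20,
        # two-sided p = 2/20 = 0.1
        out = rank_sum_screen(
            pd.DataFrame({"f": [1.0, 2.0, 3.0]}),
            pd.DataFrame({"f": [10.0, 11.0, 12.0]}),
        )
        assert out.loc["f", "p"] == pytest.approx(0.1)
        assert out.loc["f", "tier"] == "~"

    def test_tier_thresholds(self, rng):
        strong_b = pd.DataFrame({"f": rng.normal(0, 1, 200)})
        strong_m = pd.DataFrame({"f": rng.normal(3, 1, 200)})
        out = rank_sum_screen(strong_b, strong_m)
        assert out.loc["f", "tier"] == "**"

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            rank_sum_screen(pd.DataFrame({"f": [1.0]}), pd.DataFrame({"f": [1.0, 2.0]}))
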