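"""ROC/AUC, Youden cutpoint, metrics, smoothed bootstrap, permutation
importance — all checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mixsig import (ElasticNetParams, EvaluationError, FittedModel,
                    classification_metrics, evaluate_scores, permutation_importance,
                    roc_auc, smoothed_bootstrap_ci, youden_cutpoint)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_hand_example(self):
        # pairs: (2>1), (4>1), (4>3) concordant; (2<3) discordant -> 3/4
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_pair_counting_oracle(self, trial, pair_counting_auc):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 26))
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert roc_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, toy_scores):
        scores, labels = toy_scores
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(a)
        assert roc_auc(np.argsort(np.argsort(scores)).astype(float), labels) == pytest.approx(a)


def exhaustive_youden(scores, labels):
    """Oracle: evaluate J at every midpoint threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    distinct = np.unique(scores)
    best = (None, -np.inf)
    for c in (distinct[:-1] + distinct[1:]) / 2:
        called = scores >= c
        sens = (called & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~called & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best[1] + 1e-12:
            best = (c, j)
    return best


class TestYouden:
    def test_perfect_separation_midpoint(self):
        cut, j = youden_cutpoint([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cut == pytest.approx(0.5)
        assert j == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self):
        cut, j = youden_cutpoint([1, 2, 3, 4, 5], [0, 1, 0, 1, 1])
        ocut, oj = exhaustive_youden([1, 2, 3, 4, 5], [0, 1, 0, 1, 1])
        assert cut == pytest.approx(ocut)
        assert j == pytest.approx(oj)

    @pytest.mark.parametrize("trial", range(20))
    def test_random_fixtures_match_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 30))
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)
        cut, j = youden_cutpoint(scores, labels)
        ocut, oj = exhaustive_youden(scores, labels)
        assert j == pytest.approx(oj, abs=1e-12)
        assert cut == pytest.approx(ocut, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            youden_cutpoint([1.0, 2.0], [0, 0])


class TestClassificationMetrics:
    def test_hand_confusion_table(self):
        # TP=9, FN=1 (pos scores >= 0), TN=8, FP=2
        scores = np.r_[np.ones(9), -1.0, -np.ones(8), np.ones(2)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        m = classification_metrics(scores, labels, 0.0)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)

    def test_cutpoint_below_all_scores(self):
        m = classification_metrics([1, 2, 3, 4], [0, 1, 0, 1], -10.0)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["npv"] is None  # nobody called negative


class TestSmoothedBootstrap:
    def test_bandwidth_zero_is_plain_percentile_bootstrap(self):
        rng0 = np.random.default_rng(8)
        scores = rng0.normal(size=30) + np.r_[np.zeros(15), np.ones(15)]
        labels = np.r_[np.zeros(15), np.ones(15)]
        ci_smooth0 = smoothed_bootstrap_ci(scores, labels, roc_auc, n_boot=200,
                                           seed=3, bandwidth=0.0)
        # replicate the plain percentile bootstrap by hand with the same rng
        rng = np.random.default_rng(3)
        vals = [roc_auc(scores[idx], labels[idx])
                for idx in (rng.integers(0, len(scores), len(scores)) for _ in range(200))]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert ci_smooth0 == pytest.approx((lo, hi))

    def test_ci_brackets_point_estimate(self, toy_scores):
        scores, labels = toy_scores
        auc = roc_auc(scores, labels)
        lo, hi = smoothed_bootstrap_ci(scores, labels, roc_auc, n_boot=400, seed=0)
        assert lo <= auc <= hi

    def test_degenerate_resamples_redrawn(self):
        # heavily imbalanced labels force single-class resamples
        scores = np.arange(8.0)
        labels = np.array([0, 0, 0, 0, 0, 0, 0, 1])
        lo, hi = smoothed_bootstrap_ci(scores, labels, roc_auc, n_boot=50, seed=1)
        assert 0.0 <= lo <= hi <= 1.0


def _model(features, coefs):
    return FittedModel(coefficients=pd.Series(coefs, index=features, dtype=float),
                       intercept=0.0, params=ElasticNetParams(0.5, 0.1))


class TestPermutationImportance:
    def test_zero_coefficient_zero_importance(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = pd.Series((X["a"] > 0).astype(int).to_numpy())
        model = _model(["a", "b"], [1.0, 0.0])
        table = permutation_importance(model, ["a", "b"], X, y, n_perm=50, seed=0)
        assert table.loc["b", "auc_decrease"] == 0.0
        assert table.loc["a", "auc_decrease"] > 0.1

    def test_single_perfect_feature_importance_near_half(self, rng):
        x = np.sort(rng.normal(size=60))
        X = pd.DataFrame({"a": x})
        y = pd.Series((np.arange(60) >= 30).astype(int))
        model = _model(["a"], [2.0])
        table = permutation_importance(model, ["a"], X, y, n_perm=1000, seed=5)
        # permuted AUC ~ 0.5, so importance ~ 1.0 - 0.5
        assert table.loc["a", "auc_decrease"] == pytest.approx(0.5, abs=0.05)

    def test_fixed_seed_reproducible(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = pd.Series((rng.random(30) < 0.5).astype(int))
        if y.min() == y.max():
            y.iloc[0] = 1 - y.iloc[0]
        model = _model(["a", "b"], [1.0, -0.5])
        t1 = permutation_importance(model, ["a", "b"], X, y, n_perm=100, seed=9)
        t2 = permutation_importance(model, ["a", "b"], X, y, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestBinormalCoverage:
    def test_smoothed_bootstrap_covers_closed_form_auc(self):
        """Scores from two unit-variance normals d=2 apart: the true AUC is
        Phi(2/sqrt(2)); the 95% smoothed-bootstrap CI should cover it at
        roughly the nominal rate."""
        delta = 2.0
        true_auc = norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            labels = np.r_[np.zeros(100), np.ones(100)]
            scores = np.r_[rng.normal(0, 1, 100), rng.normal(delta, 1, 100)]
            lo, hi = smoothed_bootstrap_ci(scores, labels, roc_auc, n_boot=300,
                                           seed=int(rng.integers(2 ** 31)))
            hits += lo <= true_auc <= hi
        assert hits / n_rep >= 0.85  # ~95% nominal, Monte Carlo slack


def test_evaluate_scores_report_consistency(toy_scores):
    scores, labels = toy_scores
    rep = evaluate_scores(scores, labels, n_boot=100, seed=0)
    assert rep.auc == roc_auc(scores, labels)
    m = classification_metrics(scores, labels, rep.cutpoint)
    assert rep.sensitivity == m["sensitivity"]
    assert rep.youden_j == pytest.approx(rep.sensitivity + rep.specificity - 1)
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
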