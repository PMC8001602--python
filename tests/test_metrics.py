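"""Error matrix, kappa, ROC/AUC and tri-color maps against brute-force
oracles and sklearn cross-checks."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from nglseg.metrics import (ErrorMatrix, accuracy, cohens_kappa,
                            confusion_counts, evaluate, render_result_map,
                            roc_auc)


def _concordance_auc(scores, truth):
    """Brute-force pairwise AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    pos, neg = scores[truth], scores[~truth]
    wins = ties = 0
    for sp in pos:
        wins += (sp > neg).sum()
        ties += (sp == neg).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestErrorMatrix:
    def test_perfect_prediction_has_no_confusions(self, rng):
        truth = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        em = confusion_counts(truth, truth)
        assert em.Pb == em.Pc == 0
        assert em.N == 64

    def test_inverted_prediction_has_no_agreements(self, rng):
        truth = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        em = confusion_counts(1 - truth, truth)
        assert em.Pa == em.Pd == 0

    def test_two_by_two_enumeration(self):
        em = confusion_counts(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (em.Pa, em.Pb, em.Pc, em.Pd) == (1, 1, 1, 1)

    def test_shape_and_binary_validation(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            confusion_counts(np.array([0, 2]), np.array([0, 1]))


class TestAccuracyKappa:
    def test_accuracy_values(self):
        assert accuracy(ErrorMatrix(40, 10, 20, 30)) == pytest.approx(0.70)
        assert accuracy(ErrorMatrix(5, 0, 0, 5)) == 1.0
        assert accuracy(ErrorMatrix(0, 5, 5, 0)) == 0.0

    def test_kappa_perfect_is_one(self, rng):
        truth = (rng.random((10, 10)) < 0.07).astype(np.uint8)
        assert truth.sum() > 0
        em = confusion_counts(truth, truth)
        assert cohens_kappa(em) == pytest.approx(1.0)

    def test_kappa_constant_prediction_is_zero(self, rng):
        truth = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        em = confusion_counts(np.ones_like(truth), truth)
        assert cohens_kappa(em) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_worked_matrix(self):
        em = ErrorMatrix(40, 10, 20, 30)
        # brute force: Po = 0.7, Pe = 0.5*0.6 + 0.5*0.4 = 0.5
        assert cohens_kappa(em) == pytest.approx((0.7 - 0.5) / (1 - 0.5))
        assert cohens_kappa(em) == pytest.approx(0.4)

    def test_kappa_invariant_under_fp_fn_swap(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 100, size=4)
            if a + b + c + d == 0:
                continue
            k1 = cohens_kappa(ErrorMatrix(a, b, c, d))
            k2 = cohens_kappa(ErrorMatrix(a, c, b, d))
            if np.isnan(k1):
                assert np.isnan(k2)
            else:
                assert k1 == pytest.approx(k2)

    def test_kappa_range_and_perfection_condition(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 50, size=4)
            if a + b + c + d == 0:
                continue
            k = cohens_kappa(ErrorMatrix(a, b, c, d))
            if np.isnan(k):
                continue
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
            if k == pytest.approx(1.0):
                assert b == 0 and c == 0

    def test_kappa_matches_sklearn(self, rng):
        for _ in range(20):
            truth = (rng.random(200) < 0.2).astype(int)
            pred = (rng.random(200) < 0.3).astype(int)
            if len(set(truth)) < 2 or len(set(pred)) < 2:
                continue
            ours = cohens_kappa(confusion_counts(pred, truth))
            assert ours == pytest.approx(cohen_kappa_score(truth, pred))

    def test_degenerate_identical_marginals_flagged(self):
        assert np.isnan(cohens_kappa(ErrorMatrix(10, 0, 0, 0)))


class TestRoc:
    def test_perfectly_ranked_scores(self):
        truth = np.array([1, 1, 0, 0])
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), truth).auc == 1.0
        assert roc_auc(truth.astype(float), truth).auc == 1.0

    def test_four_pixel_concordance_example(self):
        curve = roc_auc(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0]))
        assert curve.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(100)
        truth = (rng.random(100) < 0.3).astype(int)
        curve = roc_auc(scores, truth)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_bruteforce_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 101))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        truth = (rng.random(n) < 0.4).astype(int)
        if truth.sum() in (0, n):
            truth[0], truth[1] = 0, 1
        assert roc_auc(scores, truth).auc == pytest.approx(
            _concordance_auc(scores, truth))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.2, 0.8]), np.array([1, 1]))


class TestResultMap:
    RED, BLUE, YELLOW = (255, 0, 0), (0, 0, 255), (255, 255, 0)

    def _count(self, img, color):
        return int(np.all(img == color, axis=-1).sum())

    def test_perfect_prediction_no_blue_no_yellow(self, rng):
        truth = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        img = render_result_map(truth, truth)
        assert self._count(img, self.BLUE) == 0
        assert self._count(img, self.YELLOW) == 0

    def test_all_positive_prediction(self, rng):
        truth = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        img = render_result_map(np.ones_like(truth), truth)
        em = confusion_counts(np.ones_like(truth), truth)
        assert self._count(img, self.BLUE) == em.Pb
        assert self._count(img, self.YELLOW) == 0

    def test_one_of_each_outcome(self):
        truth = np.array([[1, 1, 0], [0, 0, 0], [0, 0, 0]], dtype=np.uint8)
        pred = np.array([[1, 0, 1], [0, 0, 0], [0, 0, 0]], dtype=np.uint8)
        img = render_result_map(pred, truth)
        assert self._count(img, self.RED) == 1
        assert self._count(img, self.YELLOW) == 1
        assert self._count(img, self.BLUE) == 1


class TestEvaluate:
    def test_perfect_scores(self, rng):
        truth = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        rep = evaluate(truth.astype(float), truth)
        assert (rep.auc, rep.tpr, rep.fpr, rep.acc, rep.kappa) == \
               pytest.approx((1.0, 1.0, 0.0, 1.0, 1.0))

    def test_all_background_prediction(self, rng):
        truth = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        rep = evaluate(np.full(truth.shape, 0.1), truth)
        assert rep.tpr == 0.0 and rep.fpr == 0.0

    def test_worked_error_matrix_row(self):
        em = ErrorMatrix(40, 10, 20, 30)
        assert accuracy(em) == pytest.approx(0.7)
        assert cohens_kappa(em) == pytest.approx(0.4)

    def test_accuracy_identity_with_rates(self, rng):
        truth = (rng.random(400) < 0.25).astype(np.uint8)
        scores = rng.random(400)
        rep = evaluate(scores, truth)
        prev = truth.mean()
        assert rep.acc == pytest.approx(
            rep.tpr * prev + (1 - rep.fpr) * (1 - prev))
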