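import numpy as np
import pytest

from sapnet import (
    FormatError,
    confusion_metrics,
    kfold_cv,
    roc_auc,
    youden_threshold,
)
from sapnet.evaluation import replace_shallow
from sapnet.io_formats import ScoreVector
from conftest import make_sap


def pairwise_auc(scores, labels):
    """Independent oracle: mean over (pos, neg) pairs of [p > n] + 0.5 [tie]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_hand_arithmetic_on_2x2_table(self):
        # tp=3, fp=1, tn=5, fn=1
        preds = [1] * 3 + [1] + [0] * 5 + [0]
        labels = [1] * 3 + [0] + [0] * 5 + [1]
        rep = confusion_metrics(preds, labels)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 5, 1)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(5 / 6)
        assert rep.mcc == pytest.approx(14 / 24)

    def test_perfect_predictions(self):
        rep = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert rep.accuracy == 1.0 and rep.mcc == 1.0

    def test_zero_marginal_mcc_convention(self):
        rep = confusion_metrics([1, 1, 1], [1, 0, 1])
        assert rep.mcc == 0.0

    def test_count_identities(self, rng):
        preds = rng.integers(0, 2, 50)
        labels = rng.integers(0, 2, 50)
        rep = confusion_metrics(preds, labels)
        assert rep.tp + rep.fn == labels.sum()
        assert rep.tn + rep.fp == (1 - labels).sum()
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 50)

    def test_empty_is_error(self):
        with pytest.raises(FormatError):
            confusion_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_is_error(self):
        with pytest.raises(FormatError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_matches_pairwise_oracle_including_ties(self, rng):
        for n in (5, 20, 100, 200):
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.integers(0, 2, n)
            if len(set(labels.tolist())) < 2:
                labels[0], labels[1] = 0, 1
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)

    def test_null_scores_near_half(self, rng):
        scores = rng.uniform(0, 1, 2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_order_invariance(self, rng):
        scores = rng.uniform(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        perm = rng.permutation(60)
        assert roc_auc(scores, labels) == roc_auc(scores[perm], labels[perm])


class TestYoudenThreshold:
    def test_bimodal_perfect_separation(self, rng):
        neu = rng.uniform(0, 0.3, 20)
        dele = rng.uniform(0.7, 1.0, 20)
        scores = np.concatenate([neu, dele])
        labels = [0] * 20 + [1] * 20
        thr = youden_threshold(scores, labels)
        assert neu.max() < thr <= dele.min()

    def test_constant_scores(self):
        with pytest.warns(UserWarning):
            thr = youden_threshold([0.4, 0.4, 0.4], [0, 1, 0])
        assert thr == 0.4

    def test_anti_separation_warns(self):
        with pytest.warns(UserWarning, match="J"):
            youden_threshold([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])

    def test_matches_exhaustive_scan(self, rng):
        scores = rng.choice(np.linspace(0, 1, 9), 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        pos, neg = scores[np.array(labels) == 1], scores[np.array(labels) == 0]
        best = max(
            ((np.mean(pos >= t) + np.mean(neg < t) - 1, t)
             for t in np.unique(scores)),
            key=lambda jt: (jt[0], jt[1]),
        )
        assert youden_threshold(scores, labels) == best[1]


def synthetic_scored(n_pos, n_neg, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_pos + n_neg):
        label = "deleterious" if k < n_pos else "neutral"
        mu = 0.7 if label == "deleterious" else 0.3
        sv = ScoreVector(sap=make_sap(f"P{k}", k + 1, "G", "D", label=label))
        sv.s_score = float(np.clip(rng.normal(mu, 0.2), 0, 1))
        sv.t_norm = float(np.clip(rng.normal(mu, 0.25), 0, 1))
        sv.i_score = int(rng.random() < (0.4 if label == "deleterious" else 0.05))
        rows.append(sv)
    return rows


class TestKfoldCv:
    def test_determinism(self):
        rows = synthetic_scored(40, 80, seed=3)
        a = kfold_cv(rows, k=5, seed=9)
        b = kfold_cv(rows, k=5, seed=9)
        assert a.pooled == b.pooled
        assert a.held_out.equals(b.held_out)

    def test_pooled_counts_equal_sum_of_folds(self):
        rows = synthetic_scored(40, 80, seed=3)
        cv = kfold_cv(rows, k=5, seed=0)
        for m in ("tp", "fp", "tn", "fn"):
            assert getattr(cv.pooled, m) == sum(
                getattr(r, m) for r in cv.fold_reports)

    def test_leave_one_out_boundary(self):
        rows = synthetic_scored(10, 10, seed=1)
        cv = kfold_cv(rows, k=10, seed=0)
        assert len(cv.fold_reports) == 10
        assert cv.pooled.total == 20

    def test_too_large_k_is_error(self):
        rows = synthetic_scored(3, 40, seed=0)
        with pytest.raises(FormatError, match="smaller k"):
            kfold_cv(rows, k=10, seed=0)

    def test_meta_beats_or_matches_components_on_planted_signal(self):
        rows = synthetic_scored(150, 450, seed=5)
        cv = kfold_cv(rows, k=10, seed=0)
        for comp in ("s", "t", "i"):
            assert cv.component_auc["meta"] >= cv.component_auc[comp] - 0.02


class TestReplaceShallow:
    def test_strips_weights_and_meta(self):
        sv = synthetic_scored(1, 1, 0)[0]
        sv.meta_score, sv.w_s = 0.7, 0.4
        fresh = replace_shallow(sv)
        assert fresh.meta_score == 0.0 and fresh.w_s == 0.0
        assert fresh.s_score == sv.s_score and fresh.sap is sv.sap
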