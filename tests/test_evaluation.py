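"""Metric oracles: confusion counts, SE/SP/ACC ratios, ROC/AUC equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import mann_whitney_auc
from sfanet.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    confusion,
    evaluate,
    roc_auc,
    se_sp_acc,
)

RNG = np.random.default_rng(41)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        gt = (RNG.random((9, 9)) > 0.7).astype(np.uint8)
        fov = np.ones_like(gt)
        c = confusion(gt.astype(float), gt, fov, threshold=0.4)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == gt.sum() and c.tn == (1 - gt).sum()

    def test_counts_match_exhaustive_enumeration(self):
        prob = RNG.random((3, 3))
        gt = (RNG.random((3, 3)) > 0.5).astype(np.uint8)
        fov = np.ones((3, 3), dtype=np.uint8)
        c = confusion(prob, gt, fov, threshold=0.5)
        tp = fp = tn = fn = 0
        for i in range(3):
            for j in range(3):
                pred = prob[i, j] >= 0.5
                if pred and gt[i, j]:
                    tp += 1
                elif pred and not gt[i, j]:
                    fp += 1
                elif not pred and gt[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_empty_fov_gives_zero_counts_and_undefined_metrics(self):
        prob = RNG.random((4, 4))
        gt = np.zeros((4, 4), dtype=np.uint8)
        c = confusion(prob, gt, np.zeros_like(gt), 0.5)
        assert c.total == 0
        with pytest.raises(UndefinedMetricError):
            se_sp_acc(c)

    def test_counts_cover_exactly_the_fov(self):
        prob = RNG.random((8, 8))
        gt = (RNG.random((8, 8)) > 0.5).astype(np.uint8)
        fov = (RNG.random((8, 8)) > 0.4).astype(np.uint8)
        gt &= fov
        assert confusion(prob, gt, fov, 0.5).total == int(fov.sum())

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.zeros((2, 2)), np.full((2, 2), 0.5), np.ones((2, 2)), 0.5)

    def test_threshold_monotonicity(self):
        prob = RNG.random((16, 16))
        gt = (RNG.random((16, 16)) > 0.6).astype(np.uint8)
        fov = np.ones_like(gt)
        prev = confusion(prob, gt, fov, 0.0)
        for thr in (0.25, 0.5, 0.75, 1.0):
            cur = confusion(prob, gt, fov, thr)
            assert cur.tp <= prev.tp and cur.tn >= prev.tn
            prev = cur


class TestRatios:
    def test_direct_substitution(self):
        se, sp, acc = se_sp_acc(ConfusionCounts(tp=2, fp=1, tn=5, fn=2))
        assert (se, sp, acc) == (0.5, 5 / 6, 0.7)

    def test_error_free_counts_give_unit_metrics(self):
        assert se_sp_acc(ConfusionCounts(3, 0, 7, 0)) == (1.0, 1.0, 1.0)

    def test_fifty_random_tuples_match_one_line_ratios(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 100, size=4)
            se, sp, acc = se_sp_acc(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert se == tp / (tp + fn)
            assert sp == tn / (fp + tn)
            assert acc == (tp + tn) / (tp + fp + tn + fn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestROC:
    def test_perfectly_separated_scores_give_auc_one(self):
        scores = np.concatenate([RNG.random(20) * 0.4, 0.6 + RNG.random(20) * 0.4])
        labels = np.concatenate([np.zeros(20), np.ones(20)])
        curve, auc = roc_auc(scores, labels)
        assert auc == 1.0
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0

    def test_chance_level_for_label_independent_scores(self):
        scores = RNG.random(20_000)
        labels = RNG.random(20_000) > 0.7
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_trapezoid_equals_pairwise_mann_whitney(self):
        scores = RNG.random(30)
        labels = RNG.random(30) > 0.5
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-10)

    def test_tied_scores_count_half(self):
        scores = np.array([0.3, 0.3, 0.3, 0.7])
        labels = np.array([0, 1, 0, 1])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_curve_is_monotone_nondecreasing(self):
        scores = RNG.random(200)
        labels = RNG.random(200) > 0.4
        curve, _ = roc_auc(scores, labels)
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_agreement_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        scores = RNG.random(500)
        labels = (scores + RNG.normal(0, 0.4, 500)) > 0.5
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auc_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(40), 2)     # force ties
        labels = rng.random(40) > 0.5
        if labels.all() or not labels.any():
            return
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-10)


class TestEvaluate:
    def test_ground_truth_as_prediction_scores_perfectly(self):
        gt = (RNG.random((12, 12)) > 0.7).astype(np.uint8)
        fov = np.ones_like(gt)
        c = confusion(gt.astype(float), gt, fov, 0.5)
        assert se_sp_acc(c) == (1.0, 1.0, 1.0)
        _, auc = roc_auc(gt.astype(float)[fov == 1], gt[fov == 1])
        assert auc == 1.0

    def test_metrics_ignore_predictions_outside_fov(self):
        prob = RNG.random((10, 10))
        gt = (RNG.random((10, 10)) > 0.5).astype(np.uint8)
        fov = np.zeros((10, 10), dtype=np.uint8)
        fov[2:8, 2:8] = 1
        gt &= fov
        base = confusion(prob, gt, fov, 0.5)
        vandalized = prob.copy()
        vandalized[fov == 0] = RNG.random((fov == 0).sum())
        after = confusion(vandalized, gt, fov, 0.5)
        assert (base.tp, base.fp, base.tn, base.fn) == \
            (after.tp, after.fp, after.tn, after.fn)

    def test_whole_image_report_is_internally_consistent(self, small_samples):
        from sfanet.network import NetworkConfig, build

        net = build(NetworkConfig(variant="baseline", base_width=4,
                                  patch_size=16), seed=0)
        report = evaluate(net, small_samples[:2], stride=16)
        se, sp, acc = se_sp_acc(report.counts)
        assert (report.se, report.sp, report.acc) == (se, sp, acc)
        assert report.counts.total == sum(int(s.fov_mask.sum())
                                          for s in small_samples[:2])
        assert len(report.per_sample) == 2
        d = report.to_dict()
        assert d["counts"]["tp"] == report.counts.tp

    def test_untrained_network_scores_near_chance(self, small_params):
        from sfanet.network import NetworkConfig, build
        from sfanet.synthetic import generate_dataset

        samples = generate_dataset(5, small_params, seed=77)
        net = build(NetworkConfig(variant="full", base_width=4, patch_size=16),
                    seed=0)
        report = evaluate(net, samples, stride=16)
        assert abs(report.auc - 0.5) < 0.1
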