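import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftirnet import (
    ConfusionCounts,
    auroc,
    bootstrap_ci,
    compare_detectors,
    confusion,
    low_concentration_summary,
    metrics,
    metrics_report,
    roc_curve_points,
)
from ftirnet.evaluation import format_report_table


def brute_force_auroc(scores, truth):
    """All-pairs oracle: wins + half-credit ties over positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct(self):
        t = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        c = confusion(t, t)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 6, 0, 0)

    def test_all_wrong(self):
        t = np.array([1, 0, 1, 0])
        c = confusion(1 - t, t)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_hand_enumerated(self):
        c = confusion([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_direct_formula_case(self):
        f1, acc, prec, rec = metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.75)
        assert f1 == pytest.approx(0.75)
        assert acc == pytest.approx(0.8)

    def test_perfect(self):
        f1, acc, prec, rec = metrics(ConfusionCounts(tp=4, fp=0, fn=0, tn=6))
        assert (f1, acc, prec, rec) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_precision_flagged_not_zeroed(self):
        f1, acc, prec, rec = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert prec is None
        assert rec == 0.0

    @settings(max_examples=50, deadline=None)
    @given(tp=st.integers(1, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_f1_identity(self, tp, fp, fn, tn):
        f1, *_ = metrics(ConfusionCounts(tp, fp, fn, tn))
        assert f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_hand_enumerated_pairs(self):
        # positives 0.35, 0.8 vs negatives 0.1, 0.4: 3 wins / 4 pairs
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 120))
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, size=n)
        if truth.sum() in (0, n):
            truth[0], truth[1] = 0, 1
        # quantized scores force plenty of ties
        scores = rng.integers(0, 6, size=n) / 5.0
        assert auroc(scores, truth) == pytest.approx(
            brute_force_auroc(scores, truth), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 2, size=60)
        truth[:2] = [0, 1]
        scores = rng.random(60)
        a = auroc(scores, truth)
        b = auroc(np.exp(3 * scores) - 1, truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        truth = rng.integers(0, 2, size=300)
        truth[:2] = [0, 1]
        scores = np.round(rng.random(300), 2)
        assert auroc(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12
        )

    def test_roc_points_integrate_to_auroc(self):
        rng = np.random.default_rng(12)
        truth = rng.integers(0, 2, size=200)
        truth[:2] = [0, 1]
        scores = rng.random(200)
        pts = roc_curve_points(scores, truth)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auroc(scores, truth), abs=1e-12)


class TestBootstrap:
    def test_degenerate_perfect_prediction(self):
        t = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        lo, hi = bootstrap_ci(
            t, t, lambda p, tr: metrics(confusion(p, tr))[1], n_boot=200, seed=0
        )
        assert (lo, hi) == (1.0, 1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 2, size=100)
        pred = np.where(rng.random(100) < 0.85, truth, 1 - truth)
        args = (pred, truth, lambda p, t: metrics(confusion(p, t))[1])
        a = bootstrap_ci(*args, n_boot=2000, seed=7)
        b = bootstrap_ci(*args, n_boot=2000, seed=7)
        assert a == b

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, size=200)
        pred = np.where(rng.random(200) < 0.8, truth, 1 - truth)
        point = metrics(confusion(pred, truth))[1]
        lo, hi = bootstrap_ci(
            pred, truth, lambda p, t: metrics(confusion(p, t))[1],
            n_boot=2000, seed=3,
        )
        assert lo <= point <= hi

    def test_ci_width_shrinks_with_n(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            truth = rng.integers(0, 2, size=n)
            pred = np.where(rng.random(n) < 0.8, truth, 1 - truth)
            lo, hi = bootstrap_ci(
                pred, truth, lambda p, t: metrics(confusion(p, t))[1],
                n_boot=1000, seed=seed,
            )
            return hi - lo

        assert width(800, 5) < width(50, 5)

    def test_mostly_undefined_metric_raises(self):
        truth = np.array([0] * 30)
        pred = np.array([0] * 30)

        def precision(p, t):
            return metrics(confusion(p, t))[2]  # None when no predicted positives

        with pytest.raises(RuntimeError, match="undefined"):
            bootstrap_ci(pred, truth, precision, n_boot=100, seed=0)


class TestReports:
    def test_report_percent_scale_and_ci(self):
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 2, size=150)
        truth[:2] = [0, 1]
        scores = np.clip(0.6 * truth + 0.3 * rng.random(150), 0, 1)
        pred = (scores >= 0.5).astype(int)
        rep = metrics_report(pred, truth, scores, n_boot=500, seed=1)
        for m in ("f1", "accuracy", "precision", "recall", "auroc"):
            val = getattr(rep, m)
            assert 0 <= val <= 100
            lo, hi = rep.ci[m]
            assert lo <= val <= hi

    def test_identical_detectors_identical_reports(self):
        truth = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        pred = np.array([1, 0, 0, 1, 0, 1, 1, 0])
        a, b = compare_detectors(pred, pred, truth, n_boot=200, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_perfect_detector_scores_100(self):
        truth = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        _, b = compare_detectors(1 - truth, truth, truth, n_boot=0)
        assert b.f1 == b.accuracy == b.precision == b.recall == 100.0

    def test_misaligned_ids_rejected(self):
        truth = np.array([1, 0])
        with pytest.raises(ValueError, match="aligned"):
            compare_detectors(
                truth, truth, truth,
                sample_ids_a=["a", "b"], sample_ids_b=["b", "a"],
            )

    def test_table_formatting_lists_all_metrics(self):
        truth = np.array([1, 0, 1, 0, 1, 0])
        rep = metrics_report(truth, truth, n_boot=0)
        table = format_report_table({"model": rep})
        for m in ("f1", "accuracy", "precision", "recall"):
            assert m in table


class TestLowConcentration:
    def test_median_of_three(self):
        s = low_concentration_summary(
            model_pred=[1, 1, 1],
            comparator_pred=[0, 0, 0],
            truth=[1, 1, 1],
            concentration_pct=[1.0, 2.0, 3.0],
        )
        assert s.n_caught_missed == 3
        assert s.median_pct == 2.0
        assert s.q1_pct == 1.5 and s.q3_pct == 2.5  # linear interpolation

    def test_no_disagreement(self):
        s = low_concentration_summary([1, 0], [1, 0], [1, 0], [5.0, 0.0])
        assert s.n_caught_missed == 0
        assert s.median_pct is None

    def test_selection_rule(self):
        # only row 0 satisfies truth=1, model=1, comparator=0
        s = low_concentration_summary(
            model_pred=[1, 1, 0, 1],
            comparator_pred=[0, 1, 0, 0],
            truth=[1, 1, 1, 0],
            concentration_pct=[2.5, 8.0, 1.0, 0.0],
        )
        assert s.n_caught_missed == 1 and s.median_pct == 2.5
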