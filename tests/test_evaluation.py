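import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitroscreen.corpus_io import ValidationError
from vitroscreen.evaluation import (
    ConfusionMatrix,
    confusion,
    euclidean_distance,
    extrapolate_total,
    metrics,
    optimal_threshold,
    project_corpus_scale,
    roc_curve,
    round_half_up,
    threshold_for_sensitivity,
)


def mann_whitney_auc(scores, gold):
    """Independent oracle: tie-adjusted pairwise-comparison probability."""
    pos = [scores[r] for r in scores if gold[r]]
    neg = [scores[r] for r in scores if not gold[r]]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        labels = {f"r{i}": i % 2 == 0 for i in range(10)}
        cm = confusion(labels, labels)
        assert (cm.fp, cm.fn) == (0, 0)
        assert cm.tp == 5 and cm.tn == 5

    def test_hand_enumerated_disagreements(self):
        gold = {"a": True, "b": True, "c": False, "d": False, "e": True}
        dec = {"a": True, "b": False, "c": True, "d": False, "e": True}
        cm = confusion(dec, gold)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 1, 1)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="b"):
            confusion({"a": True}, {"a": True, "b": False})


class TestMetrics:
    @pytest.mark.parametrize("cm,expect", [
        # printed study rows: (sens, spec, prec) at the printed precision
        (ConfusionMatrix(275, 4846, 7, 44), (0.862, 0.998, 0.975)),
        (ConfusionMatrix(316, 4851, 2, 3), (0.990, 1.000, 0.994)),
        (ConfusionMatrix(284, 4829, 24, 35), (0.890, 0.995, 0.922)),
        (ConfusionMatrix(310, 4757, 96, 9), (0.972, 0.980, 0.764)),
    ])
    def test_study_rows_to_printed_precision(self, cm, expect):
        m = metrics(cm)
        for got, want in zip((m.sensitivity, m.specificity, m.precision), expect):
            assert abs(got - want) <= 1e-3

    def test_zero_denominators_undefined(self):
        m = metrics(ConfusionMatrix(0, 10, 0, 0))
        assert m.sensitivity is None and m.precision is None
        assert m.specificity == 1.0 and m.d is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    @given(st.integers(0, 500), st.integers(0, 5000), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rate_identities(self, tp, tn, fp, fn):
        cm = ConfusionMatrix(tp, tn, fp, fn)
        if cm.total == 0:
            return
        m = metrics(cm)
        if m.sensitivity is not None:
            assert abs(m.sensitivity * cm.positives - tp) < 1e-12
        if m.specificity is not None:
            assert abs(m.specificity * cm.negatives - tn) < 1e-12


class TestEuclideanDistance:
    def test_corners(self):
        assert euclidean_distance(1.0, 1.0) == 0.0
        assert euclidean_distance(0.0, 0.0) == pytest.approx(math.sqrt(2))

    def test_human_tiab_row(self):
        m = metrics(ConfusionMatrix(275, 4846, 7, 44))
        assert round_half_up(m.d) == 0.138

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            euclidean_distance(1.2, 0.5)

    def test_monotone_in_each_argument(self):
        for fixed in (0.3, 0.8):
            ds = [euclidean_distance(s, fixed) for s in np.linspace(0, 1, 11)]
            assert all(a >= b for a, b in zip(ds, ds[1:]))
            ds = [euclidean_distance(fixed, s) for s in np.linspace(0, 1, 11)]
            assert all(a >= b for a, b in zip(ds, ds[1:]))


class TestROC:
    def test_perfect_separation(self):
        scores = {"p1": 2.0, "p2": 3.0, "n1": 0.0, "n2": 1.0}
        gold = {"p1": True, "p2": True, "n1": False, "n2": False}
        assert roc_curve(scores, gold).auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        scores = {"a": 1.0, "b": 1.0, "c": 1.0}
        gold = {"a": True, "b": False, "c": False}
        curve = roc_curve(scores, gold)
        assert curve.auc == pytest.approx(0.5)
        assert {(p.fpr, p.tpr) for p in curve.points} == {(0.0, 0.0), (1.0, 1.0)}

    def test_tie_case_matches_mann_whitney(self):
        scores = {"p1": 3, "p2": 1, "n1": 2, "n2": 0}
        gold = {"p1": True, "p2": True, "n1": False, "n2": False}
        assert roc_curve(scores, gold).auc == pytest.approx(mann_whitney_auc(scores, gold))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve({"a": 1.0}, {"a": True})

    @given(st.lists(st.tuples(st.booleans(), st.integers(0, 5)), min_size=2, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_trapezoid_auc_equals_pairwise_oracle(self, items):
        gold = {f"r{i}": lab for i, (lab, _) in enumerate(items)}
        scores = {f"r{i}": float(s) for i, (_, s) in enumerate(items)}
        if len(set(gold.values())) < 2:
            return
        assert roc_curve(scores, gold).auc == pytest.approx(mann_whitney_auc(scores, gold))

    @given(st.lists(st.tuples(st.booleans(), st.integers(0, 5)), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_step_curve_monotone_in_threshold(self, items):
        gold = {f"r{i}": lab for i, (lab, _) in enumerate(items)}
        scores = {f"r{i}": float(s) for i, (_, s) in enumerate(items)}
        if len(set(gold.values())) < 2:
            return
        curve = roc_curve(scores, gold)
        pts = sorted(curve.points, key=lambda p: p.threshold)
        for a, b in zip(pts, pts[1:]):  # raising threshold never raises TPR/FPR
            assert b.tpr <= a.tpr + 1e-12 and b.fpr <= a.fpr + 1e-12


class TestOptimalThreshold:
    def test_separable_gives_zero_distance(self):
        scores = {"p": 2.0, "q": 3.0, "n": 0.0, "m": 1.0}
        gold = {"p": True, "q": True, "n": False, "m": False}
        curve = roc_curve(scores, gold)
        t = optimal_threshold(curve)
        best = [p for p in curve.points if p.threshold == t][0]
        assert best.d == pytest.approx(0.0)
        assert t == 2.0

    def test_exhaustive_d_comparison(self):
        # threshold 1 -> (sens 1.0, spec 0.5); threshold 2 -> (sens 0.9, spec 0.99)
        scores, gold = {}, {}
        for i in range(10):
            scores[f"p{i}"] = 2.0 if i < 9 else 1.0
            gold[f"p{i}"] = True
        for i in range(100):
            scores[f"n{i}"] = 1.0 if i < 50 else (2.0 if i == 99 else 0.0)
            gold[f"n{i}"] = False
        curve = roc_curve(scores, gold)
        assert optimal_threshold(curve) == 2.0

    def test_ties_broken_toward_higher_specificity(self):
        # two operating points with equal d: (sens .8, spec 1) and (sens 1, spec .8)
        scores = {"p1": 3, "p2": 3, "p3": 3, "p4": 3, "p5": 1,
                  "n1": 0, "n2": 0, "n3": 0, "n4": 0, "n5": 1}
        gold = {k: k.startswith("p") for k in scores}
        curve = roc_curve(scores, gold)
        pts = {p.threshold: p for p in curve.points}
        assert pts[3.0].d == pytest.approx(pts[1.0].d)
        assert optimal_threshold(curve) == 3.0  # the higher-specificity point


class TestThresholdForSensitivity:
    def test_separable(self):
        scores = {"p1": 1.0, "p2": 1.0, "n1": 0.0}
        gold = {"p1": True, "p2": True, "n1": False}
        assert threshold_for_sensitivity(scores, gold, 0.95) == 1.0

    def test_needs_all_positives(self):
        scores = {"p1": 0.9, "p2": 0.8, "p3": 0.2, "n1": 0.5, "n2": 0.1}
        gold = {"p1": True, "p2": True, "p3": True, "n1": False, "n2": False}
        assert threshold_for_sensitivity(scores, gold, 0.95) == 0.2

    def test_target_one_returns_min_positive_score(self):
        scores = {"p1": 0.9, "p2": 0.3, "n1": 0.5}
        gold = {"p1": True, "p2": True, "n1": False}
        assert threshold_for_sensitivity(scores, gold, 1.0) == 0.3

    @given(st.lists(st.tuples(st.booleans(), st.floats(0, 1, width=16)), min_size=3, max_size=40),
           st.sampled_from([0.5, 0.8, 0.95, 1.0]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_achieved_sensitivity_meets_target(self, items, target):
        gold = {f"r{i}": lab for i, (lab, _) in enumerate(items)}
        scores = {f"r{i}": float(s) for i, (_, s) in enumerate(items)}
        if not any(gold.values()):
            return
        t = threshold_for_sensitivity(scores, gold, target)
        pos = [scores[r] for r in gold if gold[r]]
        assert sum(s >= t for s in pos) / len(pos) >= target


class TestProjection:
    def test_extrapolate_plain_division(self):
        assert extrapolate_total(310, 1.0) == 310
        assert extrapolate_total(66, 0.890) == pytest.approx(74.157, abs=1e-3)
        assert extrapolate_total(350, 350 / 395) == pytest.approx(395.0)

    def test_extrapolate_zero_sensitivity_rejected(self):
        with pytest.raises(ValidationError):
            extrapolate_total(10, 0.0)

    def test_corpus_scale_study_numbers(self):
        p = project_corpus_scale(30e6, 0.148, 0.954, 0.85)
        assert p.labelled_positive / 1e6 == pytest.approx(8.1, abs=0.05)
        assert p.false_positives / 1e6 == pytest.approx(3.8, abs=0.05)
        assert p.false_negatives == pytest.approx(200_000, rel=0.05)

    def test_perfect_method_has_no_errors(self):
        p = project_corpus_scale(1e6, 0.1, 1.0, 1.0)
        assert p.false_positives == 0 and p.false_negatives == 0
        assert p.labelled_positive == pytest.approx(1e5)

    def test_zero_prevalence(self):
        p = project_corpus_scale(1000, 0.0, 0.9, 0.8)
        assert p.labelled_positive == pytest.approx(0.2 * 1000)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_count_conservation(self, prev, sens, spec):
        p = project_corpus_scale(1e6, prev, sens, spec)
        positives = prev * 1e6
        assert p.true_positives + p.false_negatives == pytest.approx(positives, abs=1e-6)
        tn = (1e6 - positives) - p.false_positives
        assert p.false_positives + tn == pytest.approx(1e6 - positives, abs=1e-6)


def test_round_half_up():
    assert round_half_up(0.0005, 3) == 0.001
    assert round_half_up(0.1384, 3) == 0.138
    assert round_half_up(0.9995, 3) == 1.0
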