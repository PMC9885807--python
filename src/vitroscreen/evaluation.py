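"""Diagnostic-accuracy statistics for screening comparisons.

Sensitivity, specificity and precision from confusion counts; the
distance-to-optimum statistic ``d = sqrt((1-sens)^2 + (1-spec)^2)``,
which measures how far an operating point sits from the perfect corner
(sensitivity = specificity = 1); ROC curves over count or score
thresholds with trapezoidal AUC; sensitivity-targeted threshold
selection; and corpus-scale projection arithmetic for "what would this
strategy do across N million publications" questions.

Metric values with a zero denominator are ``None`` ("undefined"), never
0 and never an exception: a corpus with no positives has undefined
sensitivity, which a report must distinguish from perfect sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

from .corpus_io import ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Display rounding: half-up to ``ndigits`` decimals (0.0005 -> 0.001)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("Confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    """Derived proportions; ``None`` marks an undefined (0/0) value."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    d: float | None

    def rounded(self, ndigits: int = 3) -> "Metrics":
        r = lambda v: None if v is None else round_half_up(v, ndigits)
        return Metrics(r(self.sensitivity), r(self.specificity), r(self.precision), r(self.d))


def euclidean_distance(sensitivity: float, specificity: float) -> float:
    """Distance from (sensitivity, specificity) to the perfect (1, 1) corner."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValidationError("sensitivity and specificity must lie in [0, 1]")
    return math.hypot(1.0 - sensitivity, 1.0 - specificity)


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Sensitivity, specificity, precision and d from a confusion matrix."""
    if cm.total == 0:
        raise ValidationError("Cannot compute metrics for an all-zero confusion matrix")
    sens = cm.tp / cm.positives if cm.positives else None
    spec = cm.tn / cm.negatives if cm.negatives else None
    prec = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    d = euclidean_distance(sens, spec) if sens is not None and spec is not None else None
    return Metrics(sensitivity=sens, specificity=spec, precision=prec, d=d)


def confusion(decisions: Mapping[str, bool], gold: Mapping[str, bool]) -> ConfusionMatrix:
    """Tabulate decisions against gold labels over identical id sets."""
    if set(decisions) != set(gold):
        diff = sorted(set(decisions) ^ set(gold))
        raise ValidationError(f"Decision/gold id mismatch: {diff[:10]}{'...' if len(diff) > 10 else ''}")
    tp = tn = fp = fn = 0
    for rid, dec in decisions.items():
        if gold[rid]:
            tp, fn = (tp + 1, fn) if dec else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if dec else (fp, tn + 1)
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    fpr: float
    tpr: float

    @property
    def d(self) -> float:
        return euclidean_distance(self.tpr, 1.0 - self.fpr)


@dataclass(frozen=True)
class ROCCurve:
    """Empirical step ROC over "include iff score >= threshold" rules."""

    points: tuple[ROCPoint, ...]
    auc: float


def roc_curve(scores: Mapping[str, float], gold: Mapping[str, bool]) -> ROCCurve:
    """ROC over all distinct score thresholds, anchored at (0,0) and (1,1).

    One operating point per distinct score value (include iff score >=
    threshold), plus the "include nothing" anchor at threshold +inf.  AUC
    is the trapezoidal area under the step curve; with all scores tied the
    curve is the diagonal endpoints and AUC is 0.5.
    """
    if set(scores) != set(gold):
        raise ValidationError("Score/gold id mismatch")
    y = np.array([gold[rid] for rid in scores], dtype=bool)
    s = np.array([scores[rid] for rid in scores], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative label")
    points = [ROCPoint(threshold=math.inf, fpr=0.0, tpr=0.0)]
    for t in np.unique(s)[::-1]:
        included = s >= t
        points.append(ROCPoint(
            threshold=float(t),
            fpr=float((included & ~y).sum() / n_neg),
            tpr=float((included & y).sum() / n_pos),
        ))
    pts = sorted(points, key=lambda p: p.threshold)
    xs = [p.fpr for p in points]  # list runs from the inf anchor down-threshold: fpr ascending
    ys = [p.tpr for p in points]
    if xs[-1] < 1.0:  # lowest threshold did not include everything
        xs.append(1.0)
        ys.append(1.0)
    auc = float(np.trapezoid(ys, xs))
    return ROCCurve(points=tuple(pts), auc=auc)


def optimal_threshold(curve: ROCCurve) -> float:
    """Threshold of the curve point closest to the perfect corner.

    Ties broken toward higher specificity (lower FPR), then higher
    threshold.
    """
    if not curve.points:
        raise ValidationError("Empty ROC curve")
    best = min(curve.points, key=lambda p: (p.d, p.fpr, -p.threshold))
    return best.threshold


def threshold_for_sensitivity(
    scores: Mapping[str, float], gold: Mapping[str, bool], target: float = 0.95
) -> float:
    """Largest threshold whose include-set sensitivity reaches ``target``.

    Used to pick an operating point that retrieves at least the target
    fraction of relevant records on a validation set ("sensitivity 0.95
    or higher").
    """
    if not (0.0 < target <= 1.0):
        raise ValidationError("target sensitivity must lie in (0, 1]")
    pos_scores = sorted(s for rid, s in scores.items() if gold[rid])
    if not pos_scores:
        raise ValidationError("Gold standard has no positive labels")
    n_pos = len(pos_scores)
    for t in sorted(set(scores.values()), reverse=True):
        sens = sum(1 for s in pos_scores if s >= t) / n_pos
        if sens >= target:
            return float(t)
    logger.warning("No threshold reaches sensitivity %.3f; falling back to min positive score", target)
    return float(pos_scores[0])


def extrapolate_total(found: int, assumed_sensitivity: float) -> float:
    """Estimated true total given how many a method found and its sensitivity."""
    if not (0.0 < assumed_sensitivity <= 1.0):
        raise ValidationError("assumed_sensitivity must lie in (0, 1]")
    return found / assumed_sensitivity


@dataclass(frozen=True)
class CorpusProjection:
    """Projected screening outcome at corpus scale (exact real arithmetic)."""

    corpus_size: float
    prevalence: float
    labelled_positive: float
    true_positives: float
    false_positives: float
    false_negatives: float


def project_corpus_scale(
    corpus_size: float, prevalence: float, sensitivity: float, specificity: float
) -> CorpusProjection:
    """Project a method's error counts onto a corpus of ``corpus_size``.

    With P = prevalence * size true positives in the corpus, the method
    labels sensitivity*P of them plus (1-specificity)*(size-P) negatives
    as positive; (1-sensitivity)*P relevant records are wrongly excluded.
    Rounding is left to presentation.
    """
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]")
    if corpus_size <= 0:
        raise ValidationError("corpus_size must be positive")
    positives = prevalence * corpus_size
    negatives = corpus_size - positives
    tp = sensitivity * positives
    fn = (1.0 - sensitivity) * positives
    fp = (1.0 - specificity) * negatives
    return CorpusProjection(
        corpus_size=corpus_size,
        prevalence=prevalence,
        labelled_positive=tp + fp,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
    )
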