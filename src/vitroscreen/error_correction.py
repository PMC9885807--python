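"""Error-correction loop: rescreen the largest human/machine discrepancies.

After an initial training round, the records where the human label and
the calibrated machine score disagree most (|label − score|) are the
most likely to carry a human screening error.  The top-k are sent back
to an oracle (in practice, a human rescreener; in tests, ground truth),
corrected labels replace the originals, and the classifier is retrained
from scratch with the same split seed so before/after metrics are
comparable on an untouched validation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .classifier import Hyperparameters, LabeledCorpus, ScreeningClassifier, split
from .corpus_io import ValidationError
from .evaluation import Metrics, confusion, metrics, threshold_for_sensitivity


@dataclass(frozen=True)
class Discrepancy:
    record_id: str
    human_label: bool
    machine_score: float

    @property
    def magnitude(self) -> float:
        return abs(float(self.human_label) - self.machine_score)


def rank_discrepancies(labels: Mapping[str, bool], scores: Mapping[str, float],
                       k: int) -> list[Discrepancy]:
    """Top-k records by |human label − machine score|, stable by record id."""
    if set(labels) != set(scores):
        raise ValidationError("Label/score id mismatch")
    if k < 0:
        raise ValidationError("k must be non-negative")
    discs = [Discrepancy(rid, labels[rid], scores[rid]) for rid in labels]
    discs.sort(key=lambda d: (-d.magnitude, d.record_id))
    return discs[:k]


@dataclass(frozen=True)
class CorrectionReport:
    k: int
    n_reversed: int
    n_confirmed: int
    pre_threshold: float
    post_threshold: float
    pre_metrics: Metrics
    post_metrics: Metrics


def _validation_metrics_at_target(model: ScreeningClassifier, validation: LabeledCorpus,
                                  target: float) -> tuple[float, Metrics]:
    scores = model.score(validation.records)
    thr = threshold_for_sensitivity(scores, validation.labels, target)
    decisions = {rid: s >= thr for rid, s in scores.items()}
    return thr, metrics(confusion(decisions, validation.labels))


def correct_and_retrain(
    corpus: LabeledCorpus,
    model: ScreeningClassifier,
    oracle: Callable[[str], bool] | Mapping[str, bool],
    k: int = 100,
    seed: int = 0,
    train_fraction: float = 0.8,
    target_sensitivity: float = 0.95,
    params: Hyperparameters | None = None,
) -> tuple[ScreeningClassifier, CorrectionReport]:
    """One round of top-k discrepancy correction followed by retraining.

    Labels of the k largest discrepancies in the *full* labeled corpus
    are replaced by the oracle's verdicts; the corpus is then re-split
    with the same seed and the classifier retrained under the same
    hyperparameter protocol.  The report carries specificity/precision
    at the sensitivity-targeted threshold before and after, both
    measured on the re-drawn validation split.
    """
    ask = oracle.__getitem__ if isinstance(oracle, Mapping) else oracle
    scores = model.score(corpus.records)
    ranked = rank_discrepancies(corpus.labels, scores, k)

    corrections: dict[str, bool] = {}
    n_reversed = 0
    for d in ranked:
        try:
            verdict = bool(ask(d.record_id))
        except KeyError as exc:
            raise ValidationError(f"Oracle has no verdict for record {d.record_id!r}") from exc
        corrections[d.record_id] = verdict
        if verdict != d.human_label:
            n_reversed += 1

    corrected = corpus.with_labels(corrections)
    params = params or model.params

    pre_train, pre_val = split(corpus, train_fraction, seed)
    pre_thr, pre_m = _validation_metrics_at_target(model, pre_val, target_sensitivity)

    post_train, post_val = split(corrected, train_fraction, seed)
    new_model = ScreeningClassifier(params=params, seed=model.seed).fit(post_train)
    post_thr, post_m = _validation_metrics_at_target(new_model, post_val, target_sensitivity)

    report = CorrectionReport(
        k=len(ranked), n_reversed=n_reversed, n_confirmed=len(ranked) - n_reversed,
        pre_threshold=pre_thr, post_threshold=post_thr,
        pre_metrics=pre_m, post_metrics=post_m,
    )
    return new_model, report
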