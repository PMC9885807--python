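"""Orchestration of the four-method screening comparison and classifier study.

``run_comparison`` pits four strategies against a gold standard on one
corpus: human TiAb screening, human full-text screening, regex TiAb
screening (threshold 1) and regex full-text screening (threshold 2).
On synthetic corpora the human arms are simulated — full-text reviewers
see the true label; TiAb reviewers see the label *as visible from the
abstract* (a relevant record whose abstract omits the target term looks
irrelevant at TiAb stage), which is the abstract-omission mechanism that
depresses human TiAb sensitivity.  The gold standard is rebuilt the way
a review team would: reconciled full-text decisions, with cross-method
conflicts re-evaluated by a senior oracle.

``run_classifier_study`` trains the tri-gram SGD classifier, picks the
sensitivity-targeted threshold on the validation split, runs one round
of error correction, retrains, and reports both operating points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .classifier import Hyperparameters, LabeledCorpus, ScreeningClassifier, split
from .corpus_io import ValidationError
from .error_correction import CorrectionReport, correct_and_retrain
from .evaluation import (
    ConfusionMatrix,
    Metrics,
    confusion,
    metrics,
    roc_curve,
    round_half_up,
)
from .reconciliation import build_gold_standard, reconcile_all
from .regex_screener import TermPattern, count_matches, default_ogd_terms, build_term_pattern, screen_corpus
from .synthetic_corpus import ReviewerError, simulate_reviewers

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["method", "tp", "tn", "fp", "fn",
                  "sensitivity", "specificity", "precision", "d", "auc"]


@dataclass
class MethodRow:
    method: str
    cm: ConfusionMatrix
    metrics: Metrics
    auc: float | None = None
    threshold: float | None = None


@dataclass
class ComparisonReport:
    rows: list[MethodRow]
    n_records: int
    n_gold_included: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = {r.cm.total for r in self.rows}
        if len(sizes) > 1:
            raise ValidationError(f"Method rows cover different analysis-set sizes: {sizes}")

    @property
    def prevalence(self) -> float:
        return self.n_gold_included / self.n_records

    def to_dataframe(self, ndigits: int = 3) -> pd.DataFrame:
        data = []
        for r in self.rows:
            m = r.metrics.rounded(ndigits)
            data.append({
                "method": r.method, "tp": r.cm.tp, "tn": r.cm.tn, "fp": r.cm.fp, "fn": r.cm.fn,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "precision": m.precision, "d": m.d,
                "auc": None if r.auc is None else round_half_up(r.auc, ndigits),
            })
        return pd.DataFrame(data, columns=REPORT_COLUMNS)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "comparison.csv", index=False)
        payload = {
            "n_records": self.n_records,
            "n_gold_included": self.n_gold_included,
            "prevalence": self.prevalence,
            "seed": self.seed,
            "config": self.config,
            "rows": self.to_dataframe().to_dict(orient="records"),
        }
        (out / "comparison.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _tiab_apparent_labels(corpus: LabeledCorpus, pattern: TermPattern) -> dict[str, bool]:
    """Truth as visible at TiAb stage: a relevant record 'looks' relevant
    to a TiAb reviewer only if title or abstract mentions the term."""
    apparent = {}
    for r in corpus.records:
        visible = (count_matches(r.title, pattern) + count_matches(r.abstract or "", pattern)) > 0
        apparent[r.id] = corpus.labels[r.id] and visible
    return apparent


def run_comparison(
    corpus: LabeledCorpus,
    pattern: TermPattern | None = None,
    tiab_threshold: int = 1,
    fulltext_threshold: int = 2,
    reviewer_errors: Sequence[ReviewerError] | None = None,
    seed: int = 0,
    gold: Mapping[str, bool] | None = None,
    human_decisions: Mapping[str, Mapping[str, bool]] | None = None,
) -> ComparisonReport:
    """Run the four-method comparison on one corpus.

    Human decisions may be supplied (``human_decisions`` with keys
    ``human_tiab`` / ``human_fulltext``); otherwise dual review with
    arbitration is simulated from ``reviewer_errors`` (default:
    fnr = fpr = 0.05 for screeners, a perfect arbitrator).  Unless a
    ``gold`` mapping is supplied, the gold standard is rebuilt from the
    reconciled full-text decisions with ground truth as senior oracle.
    """
    pattern = pattern or build_term_pattern(default_ogd_terms())
    reviewer_errors = list(reviewer_errors) if reviewer_errors else [
        ReviewerError(0.05, 0.05), ReviewerError(0.05, 0.05), ReviewerError(0.0, 0.0)]

    # Full-text methods need full text: the analysis set is the subset that
    # has it, and the subset size is reported alongside the corpus size.
    n_total = len(corpus.records)
    analysis_records = [r for r in corpus.records if r.has_full_text]
    n_missing = n_total - len(analysis_records)
    if n_missing:
        logger.info("Analysis restricted to %d of %d records with full text",
                    len(analysis_records), n_total)
    analysis = LabeledCorpus(records=analysis_records,
                             labels={r.id: corpus.labels[r.id] for r in analysis_records})
    ids = [r.id for r in analysis.records]

    # Regex arms (scored; AUC computable).
    rx_tiab = screen_corpus(analysis.records, pattern, scope="tiab", threshold=tiab_threshold)
    rx_ft = screen_corpus(analysis.records, pattern, scope="fulltext", threshold=fulltext_threshold)
    rx_tiab_dec = {d.record_id: d.include for d in rx_tiab.decisions}
    rx_ft_dec = {d.record_id: d.include for d in rx_ft.decisions}

    # Human arms.
    if human_decisions is not None:
        human_tiab = {rid: human_decisions["human_tiab"][rid] for rid in ids}
        human_ft = {rid: human_decisions["human_fulltext"][rid] for rid in ids}
    else:
        apparent = _tiab_apparent_labels(analysis, pattern)
        human_tiab = reconcile_all(simulate_reviewers(ids, apparent, reviewer_errors,
                                                      seed=seed, stage="tiab"))
        human_ft = reconcile_all(simulate_reviewers(ids, analysis.labels, reviewer_errors,
                                                    seed=seed + 1, stage="fulltext"))

    # Gold standard: reconciled full text + senior re-evaluation of conflicts.
    if gold is None:
        gold_std = build_gold_standard(
            fulltext_reconciled=human_ft,
            other_method_decisions=[human_tiab, rx_tiab_dec, rx_ft_dec],
            senior_oracle=analysis.labels,
        )
        gold_map = gold_std.labels
    else:
        gold_map = {rid: gold[rid] for rid in ids}

    tiab_scores = {s.record_id: float(s.count) for s in rx_tiab.scores}
    ft_scores = {s.record_id: float(s.count) for s in rx_ft.scores}
    rows = [
        MethodRow("human_tiab", *_scored_row(human_tiab, gold_map)),
        MethodRow("human_fulltext", *_scored_row(human_ft, gold_map)),
        MethodRow("regex_tiab", *_scored_row(rx_tiab_dec, gold_map),
                  auc=_safe_auc(tiab_scores, gold_map), threshold=float(tiab_threshold)),
        MethodRow("regex_fulltext", *_scored_row(rx_ft_dec, gold_map),
                  auc=_safe_auc(ft_scores, gold_map), threshold=float(fulltext_threshold)),
    ]

    return ComparisonReport(
        rows=rows, n_records=len(ids), n_gold_included=sum(gold_map.values()), seed=seed,
        config={"tiab_threshold": tiab_threshold, "fulltext_threshold": fulltext_threshold,
                "reviewer_errors": [(e.fnr, e.fpr) for e in reviewer_errors],
                "n_corpus_records": n_total, "n_fulltext_missing": n_missing},
    )


def _scored_row(decisions: Mapping[str, bool], gold: Mapping[str, bool]
                ) -> tuple[ConfusionMatrix, Metrics]:
    cm = confusion({rid: decisions[rid] for rid in gold}, gold)
    return cm, metrics(cm)


def _safe_auc(scores: Mapping[str, float], gold: Mapping[str, bool]) -> float | None:
    try:
        return roc_curve(scores, {rid: gold[rid] for rid in scores}).auc
    except ValidationError:
        return None


@dataclass
class StudyReport:
    """Classifier performance before and after one error-correction round."""

    initial_threshold: float
    corrected_threshold: float
    initial_metrics: Metrics
    corrected_metrics: Metrics
    correction: CorrectionReport
    seed: int

    def to_dataframe(self, ndigits: int = 3) -> pd.DataFrame:
        rows = []
        for name, m, thr in (("initial", self.initial_metrics, self.initial_threshold),
                             ("corrected", self.corrected_metrics, self.corrected_threshold)):
            mr = m.rounded(ndigits)
            rows.append({"stage": name, "sensitivity": mr.sensitivity,
                         "specificity": mr.specificity, "precision": mr.precision,
                         "threshold": round_half_up(thr, ndigits)})
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "classifier_study.csv", index=False)
        payload = {
            "seed": self.seed,
            "k": self.correction.k,
            "n_reversed": self.correction.n_reversed,
            "n_confirmed": self.correction.n_confirmed,
            "rows": self.to_dataframe().to_dict(orient="records"),
        }
        (out / "classifier_study.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")


def run_classifier_study(
    corpus: LabeledCorpus,
    oracle: Callable[[str], bool] | Mapping[str, bool],
    train_fraction: float = 0.8,
    target_sensitivity: float = 0.95,
    k: int = 100,
    seed: int = 0,
    params: Hyperparameters | None = None,
) -> StudyReport:
    """Train, threshold for the target sensitivity, correct errors, retrain."""
    train_set, _val = split(corpus, train_fraction, seed)
    model = ScreeningClassifier(params=params, seed=seed).fit(train_set)
    _model2, report = correct_and_retrain(
        corpus, model, oracle, k=k, seed=seed, train_fraction=train_fraction,
        target_sensitivity=target_sensitivity, params=params,
    )
    return StudyReport(
        initial_threshold=report.pre_threshold,
        corrected_threshold=report.post_threshold,
        initial_metrics=report.pre_metrics,
        corrected_metrics=report.post_metrics,
        correction=report,
        seed=seed,
    )
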