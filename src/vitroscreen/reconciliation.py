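"""Dual-reviewer reconciliation and gold-standard construction.

Each record is screened by two independent reviewers; a disagreement is
arbitrated by a third.  The gold standard starts from reconciled
full-text decisions (the most complete single source) and re-evaluates,
via a senior-reviewer oracle, every record on which any other screening
method disagrees — so a method can both add records the full-text
reviewers missed and remove records they included in error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .corpus_io import ValidationError


class NeedsArbitrationError(ValueError):
    """Two reviewers disagree and no arbitration decision is available."""

    def __init__(self, record_id: str):
        self.record_id = record_id
        super().__init__(f"Record {record_id!r} needs third-reviewer arbitration")


@dataclass(frozen=True)
class ReviewSet:
    """Ordered reviewer decisions for one record at one stage."""

    record_id: str
    stage: str
    decisions: tuple[bool, ...]
    arbitration: bool | None = None

    def __post_init__(self) -> None:
        if len(self.decisions) < 2:
            raise ValidationError(f"Record {self.record_id!r}: need at least two reviewer decisions")


def reconcile(review: ReviewSet) -> bool:
    """Agreement stands; disagreement falls to the arbitration decision."""
    first, second = review.decisions[0], review.decisions[1]
    if first == second:
        return first
    if review.arbitration is None:
        raise NeedsArbitrationError(review.record_id)
    return review.arbitration


def reconcile_all(reviews: Sequence[ReviewSet]) -> dict[str, bool]:
    return {rv.record_id: reconcile(rv) for rv in reviews}


@dataclass
class GoldStandard:
    """Reference labels with per-record provenance."""

    labels: dict[str, bool]
    provenance: dict[str, str] = field(default_factory=dict)  # reconciled_fulltext | senior_reevaluation

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.provenance):
            raise ValidationError("Every gold label needs exactly one provenance entry")

    def __getitem__(self, record_id: str) -> bool:
        return self.labels[record_id]

    def n_included(self) -> int:
        return sum(self.labels.values())


def build_gold_standard(
    fulltext_reconciled: Mapping[str, bool],
    other_method_decisions: Sequence[Mapping[str, bool]],
    senior_oracle: Callable[[str], bool] | Mapping[str, bool],
) -> GoldStandard:
    """Combine reconciled full-text decisions with senior re-evaluation.

    Records every comparison method agrees on keep the full-text label;
    records any method conflicts on get the senior oracle's verdict.
    """
    ids = set(fulltext_reconciled)
    for dec in other_method_decisions:
        if not ids <= set(dec):
            missing = sorted(ids - set(dec))
            raise ValidationError(f"Comparison decisions missing ids: {missing[:10]}")
    ask = senior_oracle.__getitem__ if isinstance(senior_oracle, Mapping) else senior_oracle

    labels: dict[str, bool] = {}
    provenance: dict[str, str] = {}
    for rid in ids:
        ft = fulltext_reconciled[rid]
        if any(dec[rid] != ft for dec in other_method_decisions):
            try:
                labels[rid] = bool(ask(rid))
            except KeyError as exc:
                raise ValidationError(f"Senior oracle has no verdict for conflicted record {rid!r}") from exc
            provenance[rid] = "senior_reevaluation"
        else:
            labels[rid] = ft
            provenance[rid] = "reconciled_fulltext"
    return GoldStandard(labels=labels, provenance=provenance)
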