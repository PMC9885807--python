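"""Seeded synthetic corpora with the statistical structure of a screening study.

The generator emulates the features that drive screening-strategy
comparisons on real systematic-review corpora:

* low prevalence of relevant records (default 6.2%);
* a target experimental term (the oxygen–glucose deprivation exemplar)
  mentioned far more reliably in full text than in the abstract — the
  abstract carries a mention for only ``abstract_mention_probability``
  of relevant records, so title-and-abstract (TiAb) screening misses the
  rest;
* long-tailed integer full-text match counts (1 + Poisson, capped) and
  small TiAb counts, with a low mention rate in irrelevant records;
* a class-conditional topic vocabulary (an "in vitro" pool vs an
  "other-research" pool over a shared background) whose separation knob
  controls how learnable the include/exclude signal is; and
* dual reviewers with independent false-negative/false-positive rates
  plus third-reviewer arbitration.

Text is synthetic token streams, not prose; everything is reproducible
from the spec and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import LabeledCorpus
from .corpus_io import Record, ValidationError
from .reconciliation import ReviewSet

# Class-conditional topic pools.  Word-like numbered tokens: filler never
# collides with the screening term's surface forms.
_POS_POOL = tuple(f"vitro{s}{i:02d}" for s in ("cell", "assay", "plate", "lysate", "medium") for i in range(30))
_NEG_POOL = tuple(f"clin{s}{i:02d}" for s in ("trial", "cohort", "survey", "patient", "ward") for i in range(30))
_SHARED_POOL = tuple(f"res{s}{i:02d}" for s in ("study", "method", "result", "group", "effect",
                                                "model", "data", "figure") for i in range(30))

#: Surface forms of the target term injected into generated text, with draw
#: weights.  Each inserted surface yields exactly one pattern match.
_MENTION_SURFACES = (
    ("oxygen-glucose deprivation", 0.45),
    ("OGD", 0.35),
    ("oxygen and glucose deprivation", 0.10),
    ("deprived of oxygen and glucose", 0.10),
)


@dataclass(frozen=True)
class ReviewerError:
    """Independent per-reviewer error rates."""

    fnr: float = 0.0  # P(exclude | truly relevant)
    fpr: float = 0.0  # P(include | truly irrelevant)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fnr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise ValidationError("Reviewer error rates must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one corpus."""

    n_records: int = 5172
    prevalence: float = 0.062
    # Full-text match counts: relevant = 1 + Poisson(mean), capped.
    relevant_fulltext_mean: float = 12.0
    fulltext_cap: int = 281
    # Irrelevant records mention the term at all with this probability
    # (then 1 + Poisson(1) matches): the source of regex false positives.
    irrelevant_mention_prob: float = 0.03
    # TiAb: probability a relevant record's abstract carries >= 1 mention
    # (the complement is the abstract-omission miss mechanism).
    abstract_mention_probability: float = 0.862
    tiab_extra_mean: float = 1.0
    tiab_cap: int = 15
    irrelevant_tiab_mention_prob: float = 0.005
    # Topic-vocabulary signal: per-token rate of own-class pool words is
    # base_rate + separation * rate_scale; other-class pool words appear at
    # base_rate, the rest is shared background.
    vocab_separation: float = 0.30
    base_topic_rate: float = 0.05
    topic_rate_scale: float = 0.20
    title_tokens: int = 8
    abstract_tokens: int = 40
    body_tokens: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "irrelevant_mention_prob", "abstract_mention_probability",
                     "irrelevant_tiab_mention_prob", "vocab_separation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_records < 1:
            raise ValidationError("n_records must be positive")
        if self.fulltext_cap < 1 or self.tiab_cap < 0:
            raise ValidationError("Infeasible match-count caps")


def standard_classifier_spec(**overrides) -> SyntheticSpec:
    """The standard classifier-study corpus: n=2500, prevalence 0.30,
    overlapping topic vocabularies (separation 0.30, Bayes error > 0)."""
    base = dict(n_records=2500, prevalence=0.30, abstract_mention_probability=0.862,
                vocab_separation=0.30)
    base.update(overrides)
    return SyntheticSpec(**base)


_POS_ARR = np.array(_POS_POOL)
_NEG_ARR = np.array(_NEG_POOL)
_SHARED_ARR = np.array(_SHARED_POOL)


def _draw_tokens(rng: np.random.Generator, n: int, relevant: bool, spec: SyntheticSpec) -> list[str]:
    own_rate = spec.base_topic_rate + spec.vocab_separation * spec.topic_rate_scale
    own, other = (_POS_ARR, _NEG_ARR) if relevant else (_NEG_ARR, _POS_ARR)
    u = rng.random(n)
    tokens = _SHARED_ARR[rng.integers(len(_SHARED_ARR), size=n)].copy()
    own_mask = u < own_rate
    other_mask = (u >= own_rate) & (u < own_rate + spec.base_topic_rate)
    tokens[own_mask] = own[rng.integers(len(own), size=int(own_mask.sum()))]
    tokens[other_mask] = other[rng.integers(len(other), size=int(other_mask.sum()))]
    return tokens.tolist()


def _draw_surface(rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for surface, w in _MENTION_SURFACES:
        acc += w
        if u < acc:
            return surface
    return _MENTION_SURFACES[-1][0]


def _inject_mentions(rng: np.random.Generator, tokens: list[str], n_mentions: int) -> str:
    """Insert term surfaces at random token positions; one match each."""
    positions = sorted(rng.integers(0, len(tokens) + 1, size=n_mentions).tolist())
    out: list[str] = []
    prev = 0
    for pos, _ in zip(positions, range(n_mentions)):
        out.extend(tokens[prev:pos])
        out.append(_draw_surface(rng))
        prev = pos
    out.extend(tokens[prev:])
    return " ".join(out)


def generate_corpus(spec: SyntheticSpec, seed: int | None = None) -> LabeledCorpus:
    """Generate a labeled corpus; labels are the ground truth.

    Full text always contains the abstract verbatim, so full-text match
    counts dominate TiAb counts by construction.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[Record] = []
    labels: dict[str, bool] = {}
    for i in range(spec.n_records):
        relevant = bool(rng.random() < spec.prevalence)
        rid = f"syn-{i:06d}"

        if relevant:
            ft_count = min(1 + int(rng.poisson(spec.relevant_fulltext_mean)), spec.fulltext_cap)
            if rng.random() < spec.abstract_mention_probability:
                tiab_count = min(1 + int(rng.poisson(spec.tiab_extra_mean)), spec.tiab_cap)
            else:
                tiab_count = 0
        else:
            if rng.random() < spec.irrelevant_mention_prob:
                ft_count = min(1 + int(rng.poisson(1.0)), spec.fulltext_cap)
            else:
                ft_count = 0
            tiab_count = 1 if rng.random() < spec.irrelevant_tiab_mention_prob else 0
        tiab_count = min(tiab_count, ft_count) if ft_count else tiab_count
        ft_count = max(ft_count, tiab_count)

        title = " ".join(_draw_tokens(rng, spec.title_tokens, relevant, spec))
        abstract = _inject_mentions(rng, _draw_tokens(rng, spec.abstract_tokens, relevant, spec),
                                    tiab_count)
        body = _inject_mentions(rng, _draw_tokens(rng, spec.body_tokens, relevant, spec),
                                ft_count - tiab_count)
        full_text = f"{title}\n\n{abstract}\n\n{body}"

        records.append(Record(id=rid, title=title, abstract=abstract, full_text=full_text))
        labels[rid] = relevant
    return LabeledCorpus(records=records, labels=labels)


def flip_labels(labels: Mapping[str, bool], fraction: float, seed: int = 0,
                which: str = "include") -> dict[str, bool]:
    """Corrupt a fraction of labels to emulate human screening error.

    ``which`` selects the pool of candidates: ``include`` flips true
    labels to exclude (the dominant real-world error), ``exclude`` the
    reverse, ``any`` both.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if which == "include":
        pool = [rid for rid, lab in labels.items() if lab]
    elif which == "exclude":
        pool = [rid for rid, lab in labels.items() if not lab]
    elif which == "any":
        pool = list(labels)
    else:
        raise ValidationError(f"Unknown pool {which!r}")
    n_flip = int(round(fraction * len(pool)))
    flipped = rng.choice(len(pool), size=n_flip, replace=False) if n_flip else []
    out = dict(labels)
    for i in flipped:
        out[pool[i]] = not out[pool[i]]
    return out


def simulate_reviewers(
    record_ids: Sequence[str],
    gold: Mapping[str, bool],
    reviewer_errors: Sequence[ReviewerError],
    seed: int = 0,
    stage: str = "fulltext",
) -> list[ReviewSet]:
    """Simulate dual review with third-reviewer arbitration.

    ``reviewer_errors`` gives (fnr, fpr) for reviewers 1, 2 and (optionally)
    the arbitrator; each reviewer errs independently per record.  An
    arbitration decision is generated only where reviewers 1–2 disagree.
    """
    if len(reviewer_errors) < 2:
        raise ValidationError("Need error specs for at least two reviewers")
    rng = np.random.default_rng(seed)
    arb_err = reviewer_errors[2] if len(reviewer_errors) > 2 else ReviewerError()

    def decide(truth: bool, err: ReviewerError) -> bool:
        flip = rng.random() < (err.fnr if truth else err.fpr)
        return (not truth) if flip else truth

    reviews = []
    for rid in record_ids:
        truth = gold[rid]
        d1 = decide(truth, reviewer_errors[0])
        d2 = decide(truth, reviewer_errors[1])
        arb = decide(truth, arb_err) if d1 != d2 else None
        reviews.append(ReviewSet(record_id=rid, stage=stage, decisions=(d1, d2), arbitration=arb))
    return reviews
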