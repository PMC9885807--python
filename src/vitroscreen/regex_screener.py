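"""Term-variant pattern building and match-count screening.

A screening "term" is a multiword phrase (with its surface variants) plus
an optional abbreviation.  The compiled pattern matches any variant with
any of space, hyphen, en-/em-dash or slash between words — PDF-extracted
text and abstracts mix dash glyphs freely, so text is NFKC-normalised and
all dash glyphs collapsed to ``-`` before matching.  Phrases match
case-insensitively; abbreviations (e.g. ``OGD``) match exact-case at word
boundaries by default, to limit false hits inside other tokens.

A record's match count is the number of non-overlapping, leftmost-first
occurrences; screening includes a record when its count reaches a
threshold (threshold 1 = "mentioned at least once").
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .corpus_io import Record, ScreeningDecision, ValidationError

logger = logging.getLogger(__name__)

# Dash glyphs folded into ASCII hyphen before matching: hyphen, non-breaking
# hyphen, figure dash, en dash, em dash, minus sign.
_DASHES = "‐‑‒–—−"
_DASH_TABLE = str.maketrans({c: "-" for c in _DASHES})

#: Separator allowed between words of a phrase: spaces/tabs, dashes, slash,
#: or a single line break — a blank line is a paragraph boundary and never
#: bridged, so concatenating texts with "\n\n" keeps match counts additive.
_SEP = r"(?:[ \t\-/]|\n(?!\n)|\r(?!\n)|\r\n(?!\s*\n))+"


def normalize(text: str) -> str:
    """NFKC-normalise and fold dash glyphs to ``-``."""
    return unicodedata.normalize("NFKC", text).translate(_DASH_TABLE)


@dataclass(frozen=True)
class TermSpec:
    """One screening term: canonical word sequence, variants, abbreviation."""

    words: tuple[str, ...]
    variants: tuple[tuple[str, ...], ...] = ()
    abbrev: str | None = None

    def __post_init__(self) -> None:
        if not self.words and self.abbrev is None:
            raise ValidationError("TermSpec needs a phrase or an abbreviation")
        for seq in (self.words, *self.variants):
            if any(not w for w in seq):
                raise ValidationError(f"Empty word in term specification {seq!r}")

    def word_sequences(self) -> list[tuple[str, ...]]:
        seqs = [self.words] if self.words else []
        seqs.extend(self.variants)
        return seqs


@dataclass(frozen=True)
class MatchScore:
    """Match count for one record in one field scope."""

    record_id: str
    field_scope: str  # "tiab" | "fulltext"
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("Match count must be non-negative")


@dataclass
class TermPattern:
    """Compiled alternation over all surface variants of a term set."""

    terms: tuple[TermSpec, ...]
    case_policy: str = "abbrev_case_sensitive"
    _compiled: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("Term list must be non-empty")
        if self.case_policy not in ("insensitive", "abbrev_case_sensitive"):
            raise ValidationError(f"Unknown case policy {self.case_policy!r}")
        alternatives: list[tuple[int, str]] = []
        for term in self.terms:
            for seq in term.word_sequences():
                body = _SEP.join(re.escape(normalize(w)) for w in seq)
                alternatives.append((len(seq), rf"(?i:\b{body}\b)"))
            if term.abbrev:
                body = rf"\b{re.escape(normalize(term.abbrev))}\b"
                if self.case_policy == "insensitive":
                    body = f"(?i:{body})"
                alternatives.append((1, body))
        # Longer phrases first so the leftmost scan prefers the full phrase
        # over any shorter variant starting at the same position.
        alternatives.sort(key=lambda t: -t[0])
        object.__setattr__(self, "_compiled", re.compile("|".join(a for _, a in alternatives)))

    def finditer(self, text: str) -> Iterable[re.Match]:
        return self._compiled.finditer(normalize(text))


def build_term_pattern(
    terms: Sequence[TermSpec], case_policy: str = "abbrev_case_sensitive"
) -> TermPattern:
    """Compile a :class:`TermPattern` from term specifications."""
    return TermPattern(terms=tuple(terms), case_policy=case_policy)


def count_matches(text: str, pattern: TermPattern) -> int:
    """Number of non-overlapping, leftmost-first matches in ``text``."""
    return sum(1 for _ in pattern.finditer(text))


@dataclass
class ScreenResult:
    scores: list[MatchScore]
    decisions: list[ScreeningDecision]
    skipped_ids: list[str]

    def __iter__(self):
        return iter((self.scores, self.decisions))


def screen_corpus(
    records: Sequence[Record],
    pattern: TermPattern,
    scope: str = "tiab",
    threshold: int = 1,
    source: str | None = None,
) -> ScreenResult:
    """Score every record and decide include/exclude at ``threshold``.

    TiAb scope counts title and abstract separately and sums (a phrase
    cannot span the title/abstract boundary).  Full-text scope skips
    records without full text and reports their ids in ``skipped_ids``.
    Include ⇔ count ≥ threshold.
    """
    if scope not in ("tiab", "fulltext"):
        raise ValidationError(f"Unknown scope {scope!r}")
    if threshold < 1:
        raise ValidationError("threshold must be a positive integer")
    source = source or f"regex_{scope}"
    scores: list[MatchScore] = []
    decisions: list[ScreeningDecision] = []
    skipped: list[str] = []
    for r in records:
        if scope == "tiab":
            n = count_matches(r.title, pattern) + count_matches(r.abstract or "", pattern)
        else:
            if not r.has_full_text:
                skipped.append(r.id)
                continue
            n = count_matches(r.full_text, pattern)
        scores.append(MatchScore(record_id=r.id, field_scope=scope, count=n))
        decisions.append(
            ScreeningDecision(record_id=r.id, stage=scope, source=source, include=n >= threshold)
        )
    if skipped:
        logger.warning("Skipped %d records without full text during fulltext screening", len(skipped))
    return ScreenResult(scores=scores, decisions=decisions, skipped_ids=skipped)


def _term_from_mapping(obj: dict) -> TermSpec:
    return TermSpec(
        words=tuple(obj.get("phrase", ())),
        variants=tuple(tuple(v) for v in obj.get("variants", ())),
        abbrev=obj.get("abbrev"),
    )


def load_term_set(path: str | Path) -> list[TermSpec]:
    """Load a YAML term-set file: ``terms: [{phrase, variants, abbrev}, ...]``."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not doc or "terms" not in doc or not doc["terms"]:
        raise ValidationError(f"{path}: no terms defined")
    return [_term_from_mapping(t) for t in doc["terms"]]


def default_ogd_terms() -> list[TermSpec]:
    """The packaged oxygen–glucose deprivation (OGD) exemplar term set."""
    with resources.files("vitroscreen.data").joinpath("ogd.yaml").open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [_term_from_mapping(t) for t in doc["terms"]]
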