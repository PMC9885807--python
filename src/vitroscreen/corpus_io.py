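"""Bibliographic record and decision I/O, plus eligibility filtering.

Records carry a title, an optional abstract and an optional full text.
An *absent* abstract is distinct from an empty one: systematic-review
eligibility rules exclude records with no abstract, and that reason is
tallied separately in the :class:`ExclusionLedger`.

Supported formats: JSONL (one object per line), RFC-4180 CSV with a
header row, and RIS import for records (TY/TI/AB/LA tags; RIS never
carries full text).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: RIS reference-type tags that denote conference material.
_RIS_CONFERENCE_TYPES = {"CPAPER", "ABST", "CONF"}

CSV_COLUMNS = ["id", "title", "abstract", "full_text", "is_conference_abstract", "language"]
DECISION_COLUMNS = ["record_id", "stage", "source", "include"]

STAGES = ("tiab", "fulltext")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a corpus invariant."""


@dataclass(frozen=True)
class Record:
    """One bibliographic item.

    ``abstract`` and ``full_text`` are ``None`` when absent; the empty
    string means "present but empty" and is preserved on round-trip.
    """

    id: str
    title: str
    abstract: str | None = None
    full_text: str | None = None
    is_conference_abstract: bool = False
    language: str = "en"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("Record id must be non-empty")

    @property
    def has_abstract(self) -> bool:
        return self.abstract is not None

    @property
    def has_full_text(self) -> bool:
        return self.full_text is not None

    def tiab(self) -> str:
        """Title and abstract joined for display; matching code keeps them apart."""
        return self.title + " " + (self.abstract or "")


@dataclass(frozen=True)
class ScreeningDecision:
    """A reviewer's or method's include/exclude verdict at one stage."""

    record_id: str
    stage: str
    source: str
    include: bool

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"Unknown stage {self.stage!r}; expected one of {STAGES}")


@dataclass
class ExclusionLedger:
    """Exactly one primary exclusion reason per excluded record."""

    counts: Counter = field(default_factory=Counter)
    reasons: dict[str, str] = field(default_factory=dict)

    def record(self, record_id: str, reason: str) -> None:
        if record_id in self.reasons:
            raise ValidationError(f"Record {record_id!r} already has an exclusion reason")
        self.reasons[record_id] = reason
        self.counts[reason] += 1

    @property
    def n_excluded(self) -> int:
        return len(self.reasons)


def _stable_id(position: int, title: str) -> str:
    digest = hashlib.sha1(f"{position}\x00{title}".encode("utf-8")).hexdigest()
    return f"rec-{digest[:12]}"


def _record_from_mapping(entry: Mapping, position: int, where: str) -> Record:
    if "title" not in entry:
        raise FormatError(f"{where}: missing required field 'title'")
    rid = entry.get("id") or _stable_id(position, str(entry["title"]))
    return Record(
        id=str(rid),
        title=str(entry["title"]),
        abstract=None if entry.get("abstract") is None else str(entry["abstract"]),
        full_text=None if entry.get("full_text") is None else str(entry["full_text"]),
        is_conference_abstract=bool(entry.get("is_conference_abstract", False)),
        language=str(entry.get("language", "en")),
    )


def _check_unique_ids(records: Sequence[Record]) -> None:
    dupes = [rid for rid, n in Counter(r.id for r in records).items() if n > 1]
    if dupes:
        raise ValidationError(f"Duplicate record ids: {sorted(dupes)}")


def _read_jsonl_records(path: Path) -> list[Record]:
    records = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                entry = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            records.append(_record_from_mapping(entry, len(records), f"{path}:{lineno}"))
    return records


_TRUTHY = {"true", "1", "yes", "t"}


def _read_csv_records(path: Path) -> list[Record]:
    records = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = {"id", "title"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing CSV columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            entry: dict = dict(row)
            # Empty cell means absent unless the companion boolean says otherwise.
            for fld, companion in (("abstract", "abstract_present"), ("full_text", "full_text_present")):
                if not row.get(fld) and row.get(companion, "").strip().lower() not in _TRUTHY:
                    entry[fld] = None
            entry["is_conference_abstract"] = row.get("is_conference_abstract", "").strip().lower() in _TRUTHY
            entry["language"] = row.get("language") or "en"
            records.append(_record_from_mapping(entry, len(records), f"{path}:{lineno}"))
    return records


def _read_ris_records(path: Path) -> list[Record]:
    """Minimal RIS reader: TY, TI/T1, AB/N2, LA, ID tags; ER closes an entry."""
    records: list[Record] = []
    entry: dict[str, str] = {}

    def flush() -> None:
        if not entry:
            return
        pos = len(records)
        rid = entry.get("ID") or _stable_id(pos, entry.get("TI", ""))
        records.append(
            Record(
                id=rid,
                title=entry.get("TI", ""),
                abstract=entry.get("AB"),
                is_conference_abstract=entry.get("TY", "").upper() in _RIS_CONFERENCE_TYPES,
                language=entry.get("LA", "en").lower()[:2] or "en",
            )
        )
        entry.clear()

    tag = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if len(line) >= 6 and line[2:6] == "  - ":
                tag = line[:2].upper()
                value = line[6:].strip()
                if tag == "ER":
                    flush()
                    tag = None
                elif tag in ("T1", "N2"):
                    tag = {"T1": "TI", "N2": "AB"}[tag]
                    entry[tag] = value
                elif tag in ("TY", "TI", "AB", "LA", "ID"):
                    entry[tag] = value
            elif tag in ("TI", "AB"):
                entry[tag] = entry.get(tag, "") + " " + line.strip()
            elif tag is None and line.strip():
                raise FormatError(f"{path}:{lineno}: not a RIS tag line: {line[:40]!r}")
    flush()
    return records


def read_records(path: str | Path, format: str | None = None) -> list[Record]:
    """Read bibliographic records from ``path``.

    ``format`` is one of ``jsonl``, ``csv`` or ``ris``; when omitted it is
    inferred from the file suffix.  Records lacking an explicit id get a
    deterministic one hashed from source position and title.
    """
    path = Path(path)
    if format is None:
        format = {".jsonl": "jsonl", ".json": "jsonl", ".csv": "csv", ".ris": "ris"}.get(
            path.suffix.lower(), "jsonl"
        )
    readers = {"jsonl": _read_jsonl_records, "csv": _read_csv_records, "ris": _read_ris_records}
    if format not in readers:
        raise ValueError(f"Unknown format {format!r}")
    records = readers[format](path)
    if not records:
        logger.warning("No records read from %s", path)
    _check_unique_ids(records)
    return records


def write_records(records: Iterable[Record], path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    records = list(records)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                obj = {"id": r.id, "title": r.title, "is_conference_abstract": r.is_conference_abstract,
                       "language": r.language}
                if r.abstract is not None:
                    obj["abstract"] = r.abstract
                if r.full_text is not None:
                    obj["full_text"] = r.full_text
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS + ["abstract_present", "full_text_present"])
            for r in records:
                writer.writerow([
                    r.id, r.title, r.abstract or "", r.full_text or "",
                    str(r.is_conference_abstract).lower(), r.language,
                    str(r.abstract is not None).lower(), str(r.full_text is not None).lower(),
                ])
    else:
        raise ValueError(f"Unknown format {format!r}")


def filter_eligible(records: Sequence[Record]) -> tuple[list[Record], ExclusionLedger]:
    """Apply the analysis eligibility filter.

    Retains English-language, non-conference records that have an abstract.
    Records lacking full text are *retained* (TiAb-only analysis remains
    possible) but callers doing full-text screening must handle them.
    """
    ledger = ExclusionLedger()
    retained = []
    for r in records:
        if r.is_conference_abstract:
            ledger.record(r.id, "conference_abstract")
        elif not r.has_abstract:
            ledger.record(r.id, "no_abstract")
        elif r.language != "en":
            ledger.record(r.id, "non_english")
        else:
            retained.append(r)
    return retained, ledger


def write_decisions(
    decisions: Sequence[ScreeningDecision],
    path: str | Path,
    format: str = "csv",
    allow_empty: bool = True,
) -> None:
    if not decisions and not allow_empty:
        raise ValidationError("Refusing to write an empty decision set (allow_empty=False)")
    path = Path(path)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(DECISION_COLUMNS)
            for d in decisions:
                writer.writerow([d.record_id, d.stage, d.source, str(d.include).lower()])
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for d in decisions:
                fh.write(json.dumps({"record_id": d.record_id, "stage": d.stage,
                                     "source": d.source, "include": d.include}) + "\n")
    else:
        raise ValueError(f"Unknown format {format!r}")


def read_decisions(path: str | Path, format: str | None = None) -> list[ScreeningDecision]:
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".json") else "csv"
    out = []
    if format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                out.append(ScreeningDecision(
                    record_id=row["record_id"], stage=row["stage"], source=row["source"],
                    include=row["include"].strip().lower() in _TRUTHY,
                ))
    elif format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    obj = json.loads(line)
                    out.append(ScreeningDecision(**obj))
    else:
        raise ValueError(f"Unknown format {format!r}")
    return out
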