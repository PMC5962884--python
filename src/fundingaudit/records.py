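"""Domain types and readers/writers for bibliographic records and disclosure lists.

Every pipeline stage speaks in terms of :class:`BiblioRecord` (one publication
with its author renderings, funding-acknowledgement text and database-parsed
funding-agency strings), :class:`DisclosureEntry` (one name on a funder's
published transparency list) and :class:`SurveyOutcome` (one corresponding
author's reply to a funding-verification survey).

I/O is deliberately dumb: readers never trim, case-fold or otherwise mutate
text fields — normalization is an explicit, separate operation in
:mod:`fundingaudit.names`.  Encoding is UTF-8 everywhere; diacritics survive a
round trip untouched.

Three corpus dialects are supported:

``jsonl``
    One JSON object per line; lossless, the canonical interchange format.
``csv``
    Flat table with list fields joined on ``"; "``; lossy for per-author
    canonical identifiers (documented below).
``tab_export``
    A two-line-header, tab-separated bibliographic export with two-letter
    column tags, the family of format produced by large citation databases:

    ====  =============================================
    tag   content
    ====  =============================================
    UT    record id
    AU    authors, ``"; "``-joined raw renderings
    TI    title
    AB    abstract
    SO    journal (source title)
    PY    publication year
    PD    publication month (1-12, may be empty)
    FX    funding acknowledgement text
    FU    funding-agency strings, ``"; "``-joined
    CF    consortium flag (0/1)
    CA    corresponding-author index (may be empty)
    ====  =============================================

    Like ``csv`` it drops canonical author ids.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AuthorRendering",
    "BiblioRecord",
    "DisclosureEntry",
    "EntityDictionary",
    "EntityEntry",
    "SurveyOutcome",
    "RowError",
    "ReadResult",
    "CorpusError",
    "parse_author",
    "read_records",
    "write_records",
    "read_disclosure_list",
    "write_disclosure_list",
    "read_survey_outcomes",
    "write_survey_outcomes",
    "read_entity_dictionary",
]

YEAR_WINDOW = (1900, 2100)

SURVEY_OUTCOMES = ("confirmed", "denied", "no_reply", "invalid_address")

ENTITY_GROUPS = (
    "parent_company",
    "foundation",
    "institute_bihw",
    "north_america",
    "subsidiary_participating",
    "subsidiary_nonparticipating",
    "other_cola",
)

#: entity groups that count as the audited funder's own brand
BRAND_GROUPS = frozenset(ENTITY_GROUPS) - {"other_cola"}

#: brand groups covered by a published transparency list
PARTICIPATING_GROUPS = frozenset(
    {"parent_company", "foundation", "institute_bihw", "north_america",
     "subsidiary_participating"}
)


class CorpusError(ValueError):
    """Fatal problem with a corpus file or record (unreadable, invalid)."""


@dataclass(frozen=True)
class AuthorRendering:
    """One author name as printed on one publication.

    The same person is typically rendered inconsistently across their
    publications (full given name vs initials, diacritics present or folded,
    hyphenated surnames split, name order swapped); each rendering is kept
    verbatim in ``raw`` alongside a surname/given split.  ``canonical_id``
    identifies the underlying person and is only ever populated for synthetic
    corpora, where ground truth is known.
    """

    raw: str
    surname: str
    given: str = ""
    canonical_id: str | None = None

    def __post_init__(self) -> None:
        if not self.raw:
            raise CorpusError("author rendering with empty raw string")
        if not self.surname.strip():
            raise CorpusError(f"author rendering {self.raw!r} has empty surname")


def parse_author(raw: str, canonical_id: str | None = None) -> AuthorRendering:
    """Split a printed name into surname and given parts.

    ``"Surname, Given"`` splits on the first comma; a comma-free name is read
    as ``"Given ... Surname"`` with the last whitespace token taken as the
    surname (hyphenated surnames survive because the hyphen keeps them a
    single token).  A single token is all surname.
    """
    raw = raw.strip()
    if not raw:
        raise CorpusError("cannot parse empty author name")
    if "," in raw:
        surname, _, given = raw.partition(",")
        return AuthorRendering(raw=raw, surname=surname.strip(),
                               given=given.strip(), canonical_id=canonical_id)
    tokens = raw.split()
    if len(tokens) == 1:
        return AuthorRendering(raw=raw, surname=tokens[0], canonical_id=canonical_id)
    return AuthorRendering(raw=raw, surname=tokens[-1],
                           given=" ".join(tokens[:-1]), canonical_id=canonical_id)


@dataclass
class BiblioRecord:
    """One publication's bibliographic metadata plus funding paratext."""

    record_id: str
    title: str
    journal: str
    year: int
    authors: list[AuthorRendering]
    abstract: str = ""
    month: int | None = None
    corresponding_author_index: int | None = None
    funding_text: str = ""
    agency_strings: list[str] = field(default_factory=list)
    consortium_flag: bool = False
    #: raw names of investigators named in the funding statement, when any
    #: (most statements name none — then all authors are retained downstream)
    pi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise CorpusError("record with empty record_id")
        lo, hi = YEAR_WINDOW
        if not lo <= int(self.year) <= hi:
            raise CorpusError(
                f"record {self.record_id}: year {self.year} outside plausible "
                f"window {lo}-{hi}")
        if self.month is not None and not 1 <= int(self.month) <= 12:
            raise CorpusError(f"record {self.record_id}: month {self.month} invalid")
        if not self.authors:
            raise CorpusError(f"record {self.record_id} has no authors")
        idx = self.corresponding_author_index
        if idx is not None and not 0 <= idx < len(self.authors):
            raise CorpusError(
                f"record {self.record_id}: corresponding_author_index {idx} "
                f"out of range for {len(self.authors)} authors")


@dataclass(frozen=True)
class DisclosureEntry:
    """One name on a funder-published transparency list."""

    name_raw: str
    source_list: str = "unknown"
    person_kind: str = "unknown"

    def __post_init__(self) -> None:
        if not self.name_raw.strip():
            raise CorpusError("disclosure entry with empty name")


@dataclass(frozen=True)
class SurveyOutcome:
    """Reply (or lack of one) from a surveyed corresponding author."""

    author_key: str
    outcome: str
    named_recipients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome not in SURVEY_OUTCOMES:
            raise CorpusError(f"unknown survey outcome {self.outcome!r}")
        if self.named_recipients and self.outcome != "denied":
            raise CorpusError(
                "named_recipients only meaningful for 'denied' outcomes")


@dataclass(frozen=True)
class EntityEntry:
    canonical_name: str
    group: str
    variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in ENTITY_GROUPS:
            raise CorpusError(f"unknown entity group {self.group!r}")
        if not self.variants:
            raise CorpusError(f"entity {self.canonical_name!r} has no variants")


def _norm_variant(v: str) -> str:
    v = unicodedata.normalize("NFKD", v)
    v = "".join(c for c in v if not unicodedata.combining(c))
    return " ".join(v.lower().split())


@dataclass
class EntityDictionary:
    """Canonical funder entities, their printed variants, and brand groups."""

    entities: list[EntityEntry]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ent in self.entities:
            for v in ent.variants:
                key = _norm_variant(v)
                if key in seen and seen[key] != ent.canonical_name:
                    raise CorpusError(
                        f"variant {v!r} claimed by both {seen[key]!r} and "
                        f"{ent.canonical_name!r}")
                seen[key] = ent.canonical_name

    def variants_longest_first(self) -> list[tuple[str, EntityEntry]]:
        pairs = [(v, e) for e in self.entities for v in e.variants]
        return sorted(pairs, key=lambda p: (-len(p[0]), p[0]))


@dataclass(frozen=True)
class RowError:
    """A rejected input row: kept in the read report, never silently dropped."""

    row: int
    message: str


@dataclass
class ReadResult:
    records: list[BiblioRecord]
    errors: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

_LIST_SEP = "; "


def _record_to_obj(rec: BiblioRecord) -> dict:
    obj = asdict(rec)
    obj["authors"] = [
        {k: v for k, v in asdict(a).items() if v not in (None, "")}
        for a in rec.authors
    ]
    return obj


def _record_from_obj(obj: dict) -> BiblioRecord:
    if "record_id" not in obj or not obj.get("record_id"):
        raise CorpusError("missing record_id")
    if "authors" not in obj or not obj["authors"]:
        raise CorpusError("missing authors")
    authors = []
    for a in obj["authors"]:
        if isinstance(a, str):
            authors.append(parse_author(a))
        else:
            authors.append(AuthorRendering(
                raw=a["raw"], surname=a.get("surname", ""),
                given=a.get("given", ""), canonical_id=a.get("canonical_id")))
    return BiblioRecord(
        record_id=str(obj["record_id"]),
        title=obj.get("title", ""),
        abstract=obj.get("abstract", ""),
        journal=obj.get("journal", ""),
        year=int(obj["year"]),
        month=(None if obj.get("month") in (None, "") else int(obj["month"])),
        authors=authors,
        corresponding_author_index=(
            None if obj.get("corresponding_author_index") in (None, "")
            else int(obj["corresponding_author_index"])),
        funding_text=obj.get("funding_text", ""),
        agency_strings=list(obj.get("agency_strings", [])),
        consortium_flag=bool(obj.get("consortium_flag", False)),
        pi_names=list(obj.get("pi_names", [])),
    )


_CSV_FIELDS = [
    "record_id", "title", "abstract", "journal", "year", "month", "authors",
    "corresponding_author_index", "funding_text", "agency_strings",
    "consortium_flag", "pi_names",
]

_TAB_TAGS = ["UT", "AU", "TI", "AB", "SO", "PY", "PD", "FX", "FU", "CF", "CA"]
_TAB_HEADER = "FN fundingaudit tab export"


def _split_list(s: str) -> list[str]:
    return [p for p in s.split(_LIST_SEP) if p] if s else []


def _flat_row(rec: BiblioRecord) -> dict[str, str]:
    return {
        "record_id": rec.record_id,
        "title": rec.title,
        "abstract": rec.abstract,
        "journal": rec.journal,
        "year": str(rec.year),
        "month": "" if rec.month is None else str(rec.month),
        "authors": _LIST_SEP.join(a.raw for a in rec.authors),
        "corresponding_author_index": (
            "" if rec.corresponding_author_index is None
            else str(rec.corresponding_author_index)),
        "funding_text": rec.funding_text,
        "agency_strings": _LIST_SEP.join(rec.agency_strings),
        "consortium_flag": "1" if rec.consortium_flag else "0",
        "pi_names": _LIST_SEP.join(rec.pi_names),
    }


def _record_from_flat(row: dict[str, str]) -> BiblioRecord:
    if not row.get("record_id"):
        raise CorpusError("missing record_id")
    if not row.get("authors"):
        raise CorpusError("missing authors")
    return BiblioRecord(
        record_id=row["record_id"],
        title=row.get("title", ""),
        abstract=row.get("abstract", ""),
        journal=row.get("journal", ""),
        year=int(row["year"]),
        month=None if not row.get("month") else int(row["month"]),
        authors=[parse_author(a) for a in _split_list(row["authors"])],
        corresponding_author_index=(
            None if not row.get("corresponding_author_index")
            else int(row["corresponding_author_index"])),
        funding_text=row.get("funding_text", ""),
        agency_strings=_split_list(row.get("agency_strings", "")),
        consortium_flag=row.get("consortium_flag", "0") in ("1", "true", "True"),
        pi_names=_split_list(row.get("pi_names", "")),
    )


# ---------------------------------------------------------------------------
# public readers / writers
# ---------------------------------------------------------------------------

def read_records(path: str | Path, dialect: str = "jsonl") -> ReadResult:
    """Read a corpus file; malformed rows are collected in ``.errors``.

    An unreadable file or unknown dialect raises :class:`CorpusError`.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such corpus file: {path}")
    records: list[BiblioRecord] = []
    errors: list[RowError] = []
    if dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(_record_from_obj(json.loads(line)))
                except (CorpusError, ValueError, KeyError) as exc:
                    errors.append(RowError(i, str(exc)))
    elif dialect == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):
                try:
                    records.append(_record_from_flat(row))
                except (CorpusError, ValueError, KeyError) as exc:
                    errors.append(RowError(i, str(exc)))
    elif dialect == "tab_export":
        with path.open(encoding="utf-8") as fh:
            lines = fh.read().split("\n")
        if len(lines) < 2 or not lines[0].startswith("FN"):
            raise CorpusError(f"{path}: not a tab_export file (missing FN header)")
        tags = lines[1].split("\t")
        tag_to_field = {"UT": "record_id", "AU": "authors", "TI": "title",
                        "AB": "abstract", "SO": "journal", "PY": "year",
                        "PD": "month", "FX": "funding_text",
                        "FU": "agency_strings", "CF": "consortium_flag",
                        "CA": "corresponding_author_index"}
        for i, line in enumerate(lines[2:], start=3):
            if not line.strip():
                continue
            cells = line.split("\t")
            row = {tag_to_field[t]: (cells[j] if j < len(cells) else "")
                   for j, t in enumerate(tags) if t in tag_to_field}
            try:
                records.append(_record_from_flat(row))
            except (CorpusError, ValueError, KeyError) as exc:
                errors.append(RowError(i, str(exc)))
    else:
        raise CorpusError(f"unknown corpus dialect {dialect!r}")
    return ReadResult(records, errors)


def write_records(records: Sequence[BiblioRecord], path: str | Path,
                  dialect: str = "jsonl") -> None:
    """Write a corpus; ``jsonl`` is lossless, ``csv``/``tab_export`` drop
    per-author canonical ids (the raw rendering is re-parsed on read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_obj(rec), ensure_ascii=False))
                fh.write("\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for rec in records:
                writer.writerow(_flat_row(rec))
    elif dialect == "tab_export":
        field_to_tag = dict(zip(
            ["record_id", "authors", "title", "abstract", "journal", "year",
             "month", "funding_text", "agency_strings", "consortium_flag",
             "corresponding_author_index"],
            ["UT", "AU", "TI", "AB", "SO", "PY", "PD", "FX", "FU", "CF", "CA"]))
        fields = list(field_to_tag)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(_TAB_HEADER + "\n")
            fh.write("\t".join(field_to_tag[f] for f in fields) + "\n")
            for rec in records:
                row = _flat_row(rec)
                fh.write("\t".join(row[f] for f in fields) + "\n")
    else:
        raise CorpusError(f"unknown corpus dialect {dialect!r}")


def read_disclosure_list(path: str | Path) -> list[DisclosureEntry]:
    """Read a transparency list from CSV (columns: name[, source, kind]).

    Duplicate names across source lists are retained here — deduplication is
    the matching stage's job, where it happens on canonical persons.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such disclosure list: {path}")
    entries: list[DisclosureEntry] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise CorpusError(f"{path}: disclosure list needs a 'name' column")
        for row in reader:
            entries.append(DisclosureEntry(
                name_raw=row["name"],
                source_list=row.get("source", "unknown") or "unknown",
                person_kind=row.get("kind", "unknown") or "unknown"))
    return entries


def write_disclosure_list(entries: Iterable[DisclosureEntry],
                          path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "source", "kind"])
        for e in entries:
            writer.writerow([e.name_raw, e.source_list, e.person_kind])


def read_survey_outcomes(path: str | Path) -> list[SurveyOutcome]:
    """Read survey outcomes from CSV (author_key, outcome, named_recipients)."""
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such survey table: {path}")
    out: list[SurveyOutcome] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(SurveyOutcome(
                author_key=row["author_key"],
                outcome=row["outcome"],
                named_recipients=tuple(_split_list(row.get("named_recipients", "")))))
    return out


def write_survey_outcomes(outcomes: Iterable[SurveyOutcome],
                          path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["author_key", "outcome", "named_recipients"])
        for o in outcomes:
            writer.writerow([o.author_key, o.outcome,
                             _LIST_SEP.join(o.named_recipients)])


def read_entity_dictionary(path: str | Path) -> EntityDictionary:
    """Load a funder-entity dictionary from YAML.

    Expected shape::

        entities:
          - canonical_name: The Coca-Cola Company
            group: parent_company
            variants: ["The Coca-Cola Company", "Coca-Cola Company", ...]
    """
    import yaml

    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such entity dictionary: {path}")
    with path.open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    entities = [EntityEntry(canonical_name=e["canonical_name"],
                            group=e["group"],
                            variants=tuple(e["variants"]))
                for e in data["entities"]]
    return EntityDictionary(entities)
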