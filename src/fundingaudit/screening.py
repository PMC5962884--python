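"""Screening and eligibility cascade for funding-acknowledgement audits.

The cascade mirrors a PRISMA-style systematic review over funding paratext:

1. **substring prefilter** — case-insensitive needle search over the funding
   acknowledgement text (the database search surrogate);
2. **direct-funding screen** — keep only records whose acknowledgement
   reports *direct receipt of funding* from the audited brand, excluding
   competing-interest-only mentions, indirect funding (student grants and the
   like), other same-name brands, and database indexing errors;
3. **brand eligibility** — restrict to records funded by the parent company
   or an affiliate that participates in the transparency initiative;
4. **cohort eligibility** — the disclosure-list recreation window: drop
   records outside the disclosure period, records funded only by
   non-participating subsidiaries, and consortium-authored records; drop
   individual non-investigator authors where the statement names the
   investigators.

Every verdict is a :class:`ScreeningDecision` with exactly one reason code,
and every stage is entered into a :class:`PrismaLedger` whose conservation
invariant (input = output + excluded, reasons sum to excluded) is checked on
rendering.  Decisions are record-local: corpus order never matters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .names import normalize_raw, keys_compatible, normalize_name
from .records import (BRAND_GROUPS, PARTICIPATING_GROUPS, BiblioRecord,
                      CorpusError, EntityDictionary, _norm_variant)

__all__ = [
    "FunderMention", "ScreeningDecision", "PrismaLedger", "CueConfig",
    "prefilter_by_substring", "detect_funder_mentions",
    "classify_direct_funding", "screen_corpus", "build_sample1",
    "build_sample2", "build_transparency_cohort", "CohortResult",
    "prisma_summary", "DEFAULT_WINDOW",
]

#: disclosure window: January 2010 through December 2015, inclusive
DEFAULT_WINDOW = ((2010, 1), (2015, 12))

REASONS = {
    "substring_prefilter": ("no_needle",),
    "direct_funding_screen": ("ci_only", "indirect", "other_cola",
                              "indexing_error"),
    "brand_eligibility": ("subsidiary_nonparticipating",),
    "cohort_eligibility": ("pre_window", "post_window",
                           "subsidiary_nonparticipating", "consortium"),
}


@dataclass(frozen=True)
class FunderMention:
    """One occurrence of a funder-entity variant in a record's paratext."""

    record_id: str
    entity_canonical: str
    entity_group: str
    span: tuple[int, int]
    source: str  # funding_text | agency_strings
    variant: str


@dataclass(frozen=True)
class ScreeningDecision:
    record_id: str
    stage: str
    included: bool
    reason_code: str

    def __post_init__(self) -> None:
        if self.included and self.reason_code != "included":
            raise CorpusError("included decisions carry reason 'included'")
        if not self.included and self.reason_code not in REASONS[self.stage]:
            raise CorpusError(
                f"reason {self.reason_code!r} not valid for stage {self.stage}")


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_output: int
    reasons: dict[str, int]

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_output


@dataclass
class PrismaLedger:
    """Ordered stage-by-stage accounting of the screening flow."""

    stages: list[StageCount] = field(default_factory=list)
    decisions: list[ScreeningDecision] = field(default_factory=list)

    def add_stage(self, stage: str, decisions: Sequence[ScreeningDecision]) -> None:
        n_in = len(decisions)
        n_out = sum(d.included for d in decisions)
        reasons: dict[str, int] = {}
        for d in decisions:
            if not d.included:
                reasons[d.reason_code] = reasons.get(d.reason_code, 0) + 1
        self.stages.append(StageCount(stage, n_in, n_out, reasons))
        self.decisions.extend(decisions)

    def check_conservation(self) -> None:
        for st in self.stages:
            if st.n_input != st.n_output + st.n_excluded:
                raise CorpusError(f"ledger stage {st.stage}: counts not conserved")
            if sum(st.reasons.values()) != st.n_excluded:
                raise CorpusError(
                    f"ledger stage {st.stage}: reason tallies ≠ excluded count")


@dataclass
class CueConfig:
    """Cue phrases that operationalize 'direct receipt of funding'.

    The original screen was a manual read of every statement; a reproducible
    audit needs the rules pinned.  A brand mention counts as direct funding
    when its sentence contains a direct cue and no indirect cue; a sentence
    with a competing-interest cue marks a relationship, not funding.
    """

    direct_cues: tuple[str, ...] = (
        "funded by", "funding from", "supported by", "grant from",
        "grants from", "financial support from", "financially supported by",
    )
    ci_cues: tuple[str, ...] = (
        "consult", "speaker", "speaking", "honoraria", "honorarium",
        "advisory", "employee", "board member",
    )
    indirect_cues: tuple[str, ...] = (
        "student grant", "travel grant", "studentship", "fellowship from",
        " via ", "in-kind",
    )


_SENTENCE_SPLIT = re.compile(r"[.;]")


def prefilter_by_substring(records: Sequence[BiblioRecord], needle: str
                           ) -> tuple[list[BiblioRecord], list[ScreeningDecision]]:
    """Case-insensitive substring pre-filter on the funding text."""
    if not needle:
        raise CorpusError("prefilter needle must be non-empty")
    needle_l = needle.lower()
    kept, decisions = [], []
    for rec in records:
        hit = needle_l in rec.funding_text.lower()
        decisions.append(ScreeningDecision(
            rec.record_id, "substring_prefilter", hit,
            "included" if hit else "no_needle"))
        if hit:
            kept.append(rec)
    return kept, decisions


def detect_funder_mentions(record: BiblioRecord, dictionary: EntityDictionary
                           ) -> list[FunderMention]:
    """Find all non-overlapping entity-variant occurrences, longest first.

    Both the funding text and the database-parsed agency strings are scanned;
    each mention records where it was found.
    """
    mentions: list[FunderMention] = []
    variants = dictionary.variants_longest_first()

    def scan(text: str, source: str) -> None:
        low = _casefold_keep_len(text)
        taken: list[tuple[int, int]] = []
        for variant, ent in variants:
            pat = _casefold_keep_len(variant)
            start = 0
            while True:
                pos = low.find(pat, start)
                if pos < 0:
                    break
                end = pos + len(pat)
                if not any(s < end and pos < e for s, e in taken):
                    taken.append((pos, end))
                    mentions.append(FunderMention(
                        record.record_id, ent.canonical_name, ent.group,
                        (pos, end), source, variant))
                start = pos + 1

    scan(record.funding_text, "funding_text")
    for s in record.agency_strings:
        scan(s, "agency_strings")
    mentions.sort(key=lambda m: (m.source, m.span))
    return mentions


def _casefold_keep_len(text: str) -> str:
    # per-character lowercase so spans stay valid in the original string
    return "".join(c.lower() if len(c.lower()) == 1 else c for c in text)


def classify_direct_funding(record: BiblioRecord,
                            mentions: Sequence[FunderMention],
                            cues: CueConfig | None = None) -> ScreeningDecision:
    """Keep a record iff some brand mention sits in a direct-funding context.

    Exclusion reasons are assigned by the first matching rule in the fixed
    order ``ci_only > indirect > other_cola > indexing_error`` so that every
    excluded record carries exactly one primary reason.
    """
    cues = cues or CueConfig()
    text_low = record.funding_text.lower()
    sentences: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_SPLIT.finditer(record.funding_text):
        sentences.append((start, m.start()))
        start = m.end()
    sentences.append((start, len(record.funding_text)))

    def sentence_of(pos: int) -> tuple[int, int]:
        for s, e in sentences:
            if s <= pos <= e:
                return s, e
        return 0, len(record.funding_text)

    brand_text_mentions = [m for m in mentions
                           if m.entity_group in BRAND_GROUPS
                           and m.source == "funding_text"]
    brand_any = [m for m in mentions if m.entity_group in BRAND_GROUPS]
    other = [m for m in mentions if m.entity_group == "other_cola"]

    saw_ci = saw_indirect = False
    for m in brand_text_mentions:
        s, e = sentence_of(m.span[0])
        sent = text_low[s:e]
        if any(c in sent for c in cues.indirect_cues):
            saw_indirect = True
            continue
        if any(c in sent for c in cues.ci_cues):
            saw_ci = True
            continue
        if any(c in sent for c in cues.direct_cues):
            return ScreeningDecision(record.record_id, "direct_funding_screen",
                                     True, "included")
    if saw_ci:
        reason = "ci_only"
    elif saw_indirect:
        reason = "indirect"
    elif other and not brand_any:
        reason = "other_cola"
    else:
        # brand appears only in the parsed agency table (or nowhere in a
        # direct context): the database credited the funder in error
        reason = "indexing_error"
    return ScreeningDecision(record.record_id, "direct_funding_screen",
                             False, reason)


def screen_corpus(records: Sequence[BiblioRecord], dictionary: EntityDictionary,
                  cues: CueConfig | None = None
                  ) -> tuple[list[BiblioRecord], list[ScreeningDecision],
                             dict[str, list[FunderMention]]]:
    """Run mention detection + direct-funding classification over a corpus."""
    kept, decisions = [], []
    mention_map: dict[str, list[FunderMention]] = {}
    for rec in records:
        mentions = detect_funder_mentions(rec, dictionary)
        mention_map[rec.record_id] = mentions
        d = classify_direct_funding(rec, mentions, cues)
        decisions.append(d)
        if d.included:
            kept.append(rec)
    return kept, decisions, mention_map


def build_sample1(records: Sequence[BiblioRecord],
                  decisions: Sequence[ScreeningDecision]) -> list[BiblioRecord]:
    """All records passing the direct-funding screen — the whole brand."""
    ok = {d.record_id for d in decisions
          if d.stage == "direct_funding_screen" and d.included}
    return [r for r in records if r.record_id in ok]


def build_sample2(sample1: Sequence[BiblioRecord],
                  mention_map: dict[str, list[FunderMention]]
                  ) -> tuple[list[BiblioRecord], list[ScreeningDecision]]:
    """Restrict to records with at least one participating-group mention.

    A record funded by both the parent company and a non-participating
    bottler stays; only records whose brand mentions are *all* outside the
    participating groups are excluded (reason ``subsidiary_nonparticipating``).
    """
    kept, decisions = [], []
    for rec in sample1:
        groups = {m.entity_group for m in mention_map.get(rec.record_id, ())
                  if m.entity_group in BRAND_GROUPS}
        ok = bool(groups & PARTICIPATING_GROUPS)
        decisions.append(ScreeningDecision(
            rec.record_id, "brand_eligibility", ok,
            "included" if ok else "subsidiary_nonparticipating"))
        if ok:
            kept.append(rec)
    return kept, decisions


@dataclass
class CohortResult:
    records: list[BiblioRecord]
    decisions: list[ScreeningDecision]
    #: record_id -> retained author indices (criterion on non-investigator
    #: authors drops individuals, not records, where investigators are named)
    retained_authors: dict[str, list[int]]


def _in_window(rec: BiblioRecord,
               window: tuple[tuple[int, int], tuple[int, int]]) -> str | None:
    (y0, m0), (y1, m1) = window
    ym = (rec.year, rec.month if rec.month is not None else None)
    if rec.year < y0 or (rec.year == y0 and rec.month is not None
                         and rec.month < m0):
        return "pre_window"
    if rec.year > y1 or (rec.year == y1 and rec.month is not None
                         and rec.month > m1):
        return "post_window"
    return None


def build_transparency_cohort(
        sample1: Sequence[BiblioRecord],
        mention_map: dict[str, list[FunderMention]],
        window: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_WINDOW,
) -> CohortResult:
    """Recreate the funder's disclosure-list cohort from Sample 1.

    Applies, in order: the publication window, the participating-funder
    requirement, the consortium exclusion, and — where a funding statement
    names the investigators — removal of non-investigator authors.  Records
    lacking a month are judged on year alone; records naming no investigator
    retain all authors (the conservative reading of statements that are
    silent on the grant holder).
    """
    kept: list[BiblioRecord] = []
    decisions: list[ScreeningDecision] = []
    retained: dict[str, list[int]] = {}
    for rec in sample1:
        reason = _in_window(rec, window)
        if reason is None:
            groups = {m.entity_group for m in mention_map.get(rec.record_id, ())
                      if m.entity_group in BRAND_GROUPS}
            if not groups & PARTICIPATING_GROUPS:
                reason = "subsidiary_nonparticipating"
            elif rec.consortium_flag:
                reason = "consortium"
        ok = reason is None
        decisions.append(ScreeningDecision(
            rec.record_id, "cohort_eligibility", ok,
            "included" if ok else reason))
        if not ok:
            continue
        kept.append(rec)
        if rec.pi_names:
            pi_keys = [normalize_raw(n) for n in rec.pi_names]
            idxs = [i for i, a in enumerate(rec.authors)
                    if any(keys_compatible(normalize_name(a), k)
                           for k in pi_keys)]
            retained[rec.record_id] = idxs or list(range(len(rec.authors)))
        else:
            retained[rec.record_id] = list(range(len(rec.authors)))
    return CohortResult(kept, decisions, retained)


def prisma_summary(ledger: PrismaLedger) -> pd.DataFrame:
    """Stage table with conservation checked; raises on a pipeline bug."""
    ledger.check_conservation()
    rows = []
    for st in ledger.stages:
        rows.append({
            "stage": st.stage,
            "input": st.n_input,
            "output": st.n_output,
            "excluded": st.n_excluded,
            **{f"reason_{k}": v for k, v in sorted(st.reasons.items())},
        })
    return pd.DataFrame(rows).fillna(0)


def export_ledger(ledger: PrismaLedger, out_dir: str | Path,
                  provenance: dict | None = None) -> None:
    """Write the ledger as CSV (stage table) and JSON (stages + decisions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prisma_summary(ledger).to_csv(out_dir / "prisma_ledger.csv", index=False)
    payload = {
        "provenance": provenance or {},
        "stages": [{"stage": s.stage, "input": s.n_input, "output": s.n_output,
                    "excluded": s.n_excluded, "reasons": s.reasons}
                   for s in ledger.stages],
        "decisions": [{"record_id": d.record_id, "stage": d.stage,
                       "included": d.included, "reason": d.reason_code}
                      for d in ledger.decisions],
    }
    (out_dir / "prisma_ledger.json").write_text(
        json.dumps(payload, indent=2), encoding="utf-8")
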