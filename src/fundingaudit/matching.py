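"""Disclosure-coverage analysis: match cohort authors to transparency lists.

The audit's central question — *is the funder's published list of funded
researchers complete?* — reduces to a careful name-matching exercise between
the canonical author clusters recovered from the cohort (see
:mod:`fundingaudit.names`) and the names on the funder's transparency lists.

Matching proceeds exact-first (identical folded keys), then approximate:
candidate pairs must pass a hard surname-agreement gate and an
initial-compatibility check, and are scored with a normalized edit-distance
similarity on their aligned folded forms.  Assignment between canonical
persons is one-to-one, highest score first, ties broken lexicographically.
Scores in a configurable band below the auto-accept threshold are flagged
``needs_review`` — the pipeline stand-in for the manual verification step a
human auditor would perform — and are excluded from automatic counts unless
explicitly promoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .names import (AuthorCluster, NameKey, _tokens_compatible, keys_compatible,
                    normalize_raw)
from .records import BiblioRecord, CorpusError, DisclosureEntry, SurveyOutcome

__all__ = [
    "MatchConfig", "MatchResult", "CoverageReport", "levenshtein",
    "similarity", "score_keys", "match_author_lists", "coverage_metrics",
    "remove_matched_publications", "apply_survey_adjustments", "survey_tally",
]


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance (insert/delete/substitute, unit costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity in [0, 1]."""
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


@dataclass
class MatchConfig:
    """Thresholds for approximate name matching.

    ``auto_accept`` is the minimum score for an automatic match; scores in
    ``[review_low, auto_accept)`` are flagged for review; anything below is
    rejected.  ``promote_review`` treats reviewed matches as accepted — the
    audit's way of recording that a human confirmed them.
    """

    auto_accept: float = 0.90
    review_low: float = 0.80
    promote_review: bool = False
    #: token pairs differing by one edit (length ≥ 4) still pair, at a penalty
    fuzzy_tokens: bool = True


@dataclass(frozen=True)
class MatchResult:
    author_key: str            # canonical key of the cohort cluster
    cluster_index: int
    disclosure_name: str
    disclosure_index: int
    match_type: str            # exact | approximate
    score: float
    review_status: str         # auto_accepted | needs_review | rejected

    def __post_init__(self) -> None:
        if self.match_type == "exact" and self.score != 1.0:
            raise CorpusError("exact matches must score 1")


def _aligned_score(a: NameKey, b: NameKey, fuzzy: bool) -> float | None:
    """Score two surname-anchored keys, or None if the gate fails.

    Remaining tokens (surname prefix + given) must admit a one-to-one
    pairing; compatible pairs (equal / initial / truncation) contribute full
    similarity on their shared information, fuzzy pairs contribute their
    edit similarity.  The pair score is the product of the anchor similarity
    (1 by construction) and the minimum token-pair similarity.
    """
    if a.anchor != b.anchor:
        return None
    rest_a = list(a.surname_tokens[:-1] + a.given_tokens)
    rest_b = list(b.surname_tokens[:-1] + b.given_tokens)
    if len(rest_a) != len(rest_b):
        return None

    def pair(xs: list[str], ys: list[str]) -> float | None:
        if not xs:
            return 1.0
        x, rest = xs[0], xs[1:]
        best = None
        for i, y in enumerate(ys):
            if _tokens_compatible(x, y):
                s = 1.0
            elif (fuzzy and min(len(x), len(y)) >= 4
                  and levenshtein(x, y) <= 1):
                s = similarity(x, y)
            else:
                continue
            sub = pair(rest, ys[:i] + ys[i + 1:])
            if sub is not None:
                cand = min(s, sub)
                best = cand if best is None or cand > best else best
        return best

    return pair(rest_a, rest_b)


def score_keys(a: NameKey, b: NameKey, fuzzy: bool = True) -> float:
    """Public scoring hook: 0 when the surname gate fails."""
    s = _aligned_score(a, b, fuzzy)
    return 0.0 if s is None else s


def match_author_lists(clusters: Sequence[AuthorCluster],
                       disclosure: Sequence[DisclosureEntry],
                       config: MatchConfig | None = None) -> list[MatchResult]:
    """One-to-one matching of canonical cohort persons to disclosure names.

    Exact folded-key equality first; then approximate pairs passing the
    surname gate, assigned greedily highest-score-first with lexicographic
    tie-breaking.  Every scored pair below ``review_low`` is recorded as
    rejected so the audit trail shows what was considered.
    """
    if not clusters or not disclosure:
        raise CorpusError("matching requires non-empty author and disclosure lists")
    config = config or MatchConfig()
    if not 0.0 < config.auto_accept <= 1.0:
        raise CorpusError("auto_accept threshold must lie in (0, 1]")

    entry_keys = [normalize_raw(e.name_raw) for e in disclosure]
    candidates: list[tuple[float, str, str, int, int, str]] = []
    for ci, cl in enumerate(clusters):
        for di, ek in enumerate(entry_keys):
            best, exact = 0.0, False
            for mk in cl.members:
                if mk.full_folded == ek.full_folded:
                    best, exact = 1.0, True
                    break
                s = _aligned_score(mk, ek, config.fuzzy_tokens)
                if s is not None and s > best:
                    best = s
            if best > 0.0:
                candidates.append((best, cl.canonical_key,
                                   disclosure[di].name_raw, ci, di,
                                   "exact" if exact else "approximate"))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_clusters: set[int] = set()
    used_entries: set[str] = set()   # one-to-one on *persons*: folded name
    results: list[MatchResult] = []
    for score, ckey, dname, ci, di, mtype in candidates:
        person = entry_keys[di].full_folded
        if ci in used_clusters or person in used_entries:
            continue
        if score >= config.auto_accept:
            status = "auto_accepted"
        elif score >= config.review_low:
            status = "needs_review"
        else:
            status = "rejected"
        if status != "rejected":
            used_clusters.add(ci)
            used_entries.add(person)
        results.append(MatchResult(ckey, ci, dname, di, mtype, score, status))
    return results


def accepted_matches(results: Iterable[MatchResult],
                     config: MatchConfig | None = None) -> list[MatchResult]:
    config = config or MatchConfig()
    ok = {"auto_accepted"}
    if config.promote_review:
        ok.add("needs_review")
    return [r for r in results if r.review_status in ok]


@dataclass
class CoverageReport:
    n_cohort_authors: int
    n_disclosure_names: int
    n_matched: int
    pct_of_disclosure: float
    pct_of_cohort: float
    unmatched_disclosure_names: list[str] = field(default_factory=list)
    unmatched_author_articles: tuple[int, int] = (0, 0)  # (authors, articles)


def coverage_metrics(matches: Sequence[MatchResult],
                     clusters: Sequence[AuthorCluster],
                     disclosure: Sequence[DisclosureEntry],
                     config: MatchConfig | None = None) -> CoverageReport:
    """Counts and one-decimal percentages of disclosure coverage."""
    if not clusters:
        raise CorpusError("coverage undefined for an empty cohort")
    acc = accepted_matches(matches, config)
    matched_entry_persons = {normalize_raw(m.disclosure_name).full_folded
                             for m in acc}
    n_disc = len({normalize_raw(e.name_raw).full_folded for e in disclosure})
    n_matched = len(matched_entry_persons)
    unmatched = sorted({e.name_raw for e in disclosure
                        if normalize_raw(e.name_raw).full_folded
                        not in matched_entry_persons})
    return CoverageReport(
        n_cohort_authors=len(clusters),
        n_disclosure_names=n_disc,
        n_matched=n_matched,
        pct_of_disclosure=round(100.0 * n_matched / n_disc, 1),
        pct_of_cohort=round(100.0 * n_matched / len(clusters), 1),
        unmatched_disclosure_names=unmatched,
    )


def remove_matched_publications(
        cohort_records: Sequence[BiblioRecord],
        matches: Sequence[MatchResult],
        clusters: Sequence[AuthorCluster],
        assignment: dict[tuple[str, int], int],
        config: MatchConfig | None = None,
) -> tuple[list[BiblioRecord], list[AuthorCluster]]:
    """Drop every record listing at least one matched canonical person.

    Returns the surviving records and the deduplicated union of canonical
    persons over them — the funded authors the disclosure lists leave
    unaccounted for.
    """
    matched_clusters = {m.cluster_index for m in accepted_matches(matches, config)}
    remaining: list[BiblioRecord] = []
    for rec in cohort_records:
        cls = {assignment[(rec.record_id, i)] for i in range(len(rec.authors))}
        if cls & matched_clusters:
            continue
        remaining.append(rec)
    remaining_cluster_idx = sorted({
        assignment[(rec.record_id, i)]
        for rec in remaining for i in range(len(rec.authors))})
    return remaining, [clusters[i] for i in remaining_cluster_idx]


def apply_survey_adjustments(
        remaining: Sequence[BiblioRecord],
        remaining_clusters: Sequence[AuthorCluster],
        outcomes: Sequence[SurveyOutcome],
        assignment: dict[tuple[str, int], int],
        clusters: Sequence[AuthorCluster],
) -> tuple[list[AuthorCluster], list[BiblioRecord], list[str]]:
    """Fold corresponding-author survey replies into the unaccounted set.

    * a **denier**'s name leaves the author set (any primary grant recipients
      they named are kept);
    * a **confirmer** accounts for each of their publications: all co-author
      names on those records leave the set (the confirmer is tallied as a
      verified funding recipient, no longer "unaccounted");
    * records left with no unaccounted author are dropped.

    Outcomes naming an unknown author are reported back, not fatal.
    """
    cluster_of_key: dict[str, int] = {}
    for ci, cl in enumerate(clusters):
        for mk in cl.members:
            cluster_of_key.setdefault(mk.full_folded, ci)

    def find_cluster(raw_key: str) -> int | None:
        key = normalize_raw(raw_key)
        if key.full_folded in cluster_of_key:
            return cluster_of_key[key.full_folded]
        for ci, cl in enumerate(clusters):
            if any(keys_compatible(mk, key) for mk in cl.members):
                return ci
        return None

    removed: set[int] = set()
    kept_recipients: set[int] = set()
    problems: list[str] = []
    confirmed_clusters: set[int] = set()
    for oc in outcomes:
        ci = find_cluster(oc.author_key)
        if ci is None:
            problems.append(f"survey outcome for unknown author {oc.author_key!r}")
            continue
        if oc.outcome == "denied":
            removed.add(ci)
            for rec_name in oc.named_recipients:
                ri = find_cluster(rec_name)
                if ri is not None:
                    kept_recipients.add(ri)
                else:
                    problems.append(
                        f"named recipient {rec_name!r} not in author set")
        elif oc.outcome == "confirmed":
            confirmed_clusters.add(ci)

    for rec in remaining:
        rec_clusters = {assignment[(rec.record_id, i)]
                        for i in range(len(rec.authors))}
        ca = rec.corresponding_author_index
        ca_cluster = (assignment[(rec.record_id, ca)] if ca is not None else None)
        if ca_cluster in confirmed_clusters:
            removed |= rec_clusters
    removed -= kept_recipients

    remaining_idx = {id(cl): i for i, cl in enumerate(clusters)}
    adj_clusters = [cl for cl in remaining_clusters
                    if remaining_idx[id(cl)] not in removed]
    adj_cluster_set = {remaining_idx[id(cl)] for cl in adj_clusters}
    adj_records = []
    for rec in remaining:
        rec_clusters = {assignment[(rec.record_id, i)]
                        for i in range(len(rec.authors))}
        if rec_clusters & adj_cluster_set:
            adj_records.append(rec)
    return adj_clusters, adj_records, problems


def survey_tally(outcomes: Sequence[SurveyOutcome]
                 ) -> dict[str, dict[str, float]]:
    """Per-category counts with integer-rounded percentages (half up)."""
    if not outcomes:
        raise CorpusError("survey tally needs at least one outcome")
    total = len(outcomes)
    tally: dict[str, dict[str, float]] = {}
    for cat in ("confirmed", "denied", "no_reply", "invalid_address"):
        n = sum(o.outcome == cat for o in outcomes)
        pct = int(100.0 * n / total + 0.5)
        tally[cat] = {"count": n, "pct": pct}
    tally["total"] = {"count": total, "pct": 100}
    return tally
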