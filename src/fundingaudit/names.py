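"""Author-name normalization and canonical-person disambiguation.

Bibliographic databases print the same person many ways: ``"Müller, Jürgen"``,
``"Muller, J."``, ``"Jurgen Muller"``.  Before any counting or matching, every
rendering is folded into a :class:`NameKey` (lowercase, diacritics stripped,
punctuation removed, order-normalized), and renderings that plausibly denote
the same person are merged into clusters by :func:`dedupe_authors`.

Two keys are *compatible* — taken to denote the same person — when their
surname anchors (the last surname token) agree and their remaining name
tokens admit a one-to-one pairing in which each pair is equal, an
initial-expansion (``j`` / ``jurgen``) or a truncation (``jurg`` / ``jurgen``).
This absorbs the rendering variation above while keeping distinct surnames
apart; it deliberately stays conservative — two full distinct given names
never merge.  Same-surname people sharing a first initial are a known
ambiguity of initial-only renderings and are merged, as any string-based
disambiguator must.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import AuthorRendering, BiblioRecord, CorpusError, parse_author

__all__ = ["NameKey", "normalize_name", "keys_compatible", "dedupe_authors",
           "AuthorCluster", "cluster_records", "normalize_raw"]


def _fold(text: str) -> str:
    """Lowercase, strip diacritics, map punctuation to spaces, squeeze."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(c for c in text if not unicodedata.combining(c))
    out = []
    for ch in text.lower():
        if ch.isalpha() or ch.isspace():
            out.append(ch)
        else:
            out.append(" ")
    return " ".join("".join(out).split())


@dataclass(frozen=True)
class NameKey:
    """Folded, order-normalized representation of one author rendering."""

    surname_tokens: tuple[str, ...]
    given_tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.surname_tokens:
            raise CorpusError("name folded to an empty surname")

    @property
    def surname_folded(self) -> str:
        return " ".join(self.surname_tokens)

    @property
    def full_folded(self) -> str:
        return " ".join(self.surname_tokens + self.given_tokens)

    @property
    def anchor(self) -> str:
        """Last surname token — the stable indexing handle of the name."""
        return self.surname_tokens[-1]


def normalize_name(rendering: AuthorRendering) -> NameKey:
    """Fold one rendering into a :class:`NameKey`.

    ``"Surname, Given"`` and ``"Given Surname"`` orders yield identical keys;
    hyphenated surnames split into their component tokens.
    """
    surname_tokens = tuple(_fold(rendering.surname).split())
    given_tokens = tuple(_fold(rendering.given).split())
    if not surname_tokens:
        raise CorpusError(
            f"rendering {rendering.raw!r} has empty surname after folding")
    return NameKey(surname_tokens, given_tokens)


def normalize_raw(raw: str) -> NameKey:
    """Convenience: parse then normalize a raw printed name."""
    return normalize_name(parse_author(raw))


def _tokens_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) == 1:                      # initial vs full token
        return long_.startswith(short)
    if len(short) >= 3:                      # truncated given name
        return long_.startswith(short)
    return False


def _pairing_exists(xs: Sequence[str], ys: Sequence[str]) -> bool:
    """Perfect one-to-one pairing of xs with ys under token compatibility
    (backtracking; name-token lists are tiny)."""
    if len(xs) != len(ys):
        return False
    if not xs:
        return True
    x, rest = xs[0], xs[1:]
    for i, y in enumerate(ys):
        if _tokens_compatible(x, y):
            if _pairing_exists(rest, ys[:i] + ys[i + 1:]):
                return True
    return False


def keys_compatible(a: NameKey, b: NameKey) -> bool:
    """True when the two keys plausibly denote the same person."""
    if a.anchor != b.anchor:
        return False
    rest_a = list(a.surname_tokens[:-1] + a.given_tokens)
    rest_b = list(b.surname_tokens[:-1] + b.given_tokens)
    return _pairing_exists(tuple(rest_a), tuple(rest_b))


@dataclass
class AuthorCluster:
    """One inferred canonical person: every rendering folded into it."""

    key: NameKey                      # most informative member key
    members: list[NameKey]
    renderings: list[AuthorRendering]

    @property
    def canonical_key(self) -> str:
        return self.key.full_folded


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def dedupe_authors(renderings: Iterable[AuthorRendering]) -> list[AuthorCluster]:
    """Merge author renderings into canonical-person clusters.

    Renderings are bucketed by surname anchor, then merged transitively by
    pairwise key compatibility (union-find).  The cluster representative is
    the member with the longest folded form — the most informative rendering.
    Deterministic: output sorted by canonical key.
    """
    rends = list(renderings)
    keys = [normalize_name(r) for r in rends]
    order = sorted(range(len(rends)), key=lambda i: keys[i].full_folded)
    uf = _UnionFind(len(rends))
    buckets: dict[str, list[int]] = {}
    for i in order:
        buckets.setdefault(keys[i].anchor, []).append(i)
    for idxs in buckets.values():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if uf.find(i) != uf.find(j) and keys_compatible(keys[i], keys[j]):
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(rends)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for idxs in groups.values():
        rep = max(idxs, key=lambda i: (len(keys[i].full_folded),
                                       keys[i].full_folded))
        clusters.append(AuthorCluster(
            key=keys[rep],
            members=[keys[i] for i in idxs],
            renderings=[rends[i] for i in idxs]))
    clusters.sort(key=lambda c: c.canonical_key)
    return clusters


def cluster_records(records: Iterable[BiblioRecord]
                    ) -> tuple[list[AuthorCluster], dict[tuple[str, int], int]]:
    """Cluster every author rendering across a record set.

    Returns the clusters plus a map ``(record_id, author_index) -> cluster
    index`` so downstream stages can ask which canonical person each byline
    position denotes.
    """
    records = list(records)
    flat: list[AuthorRendering] = []
    where: list[tuple[str, int]] = []
    for rec in records:
        for i, a in enumerate(rec.authors):
            flat.append(a)
            where.append((rec.record_id, i))
    clusters = dedupe_authors(flat)
    rend_to_cluster: dict[int, int] = {}
    for ci, cl in enumerate(clusters):
        for r in cl.renderings:
            rend_to_cluster[id(r)] = ci
    assignment = {where[i]: rend_to_cluster[id(flat[i])]
                  for i in range(len(flat))}
    return clusters, assignment
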