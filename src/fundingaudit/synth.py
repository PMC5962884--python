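"""Synthetic corpora with planted ground truth.

Real funding-audit corpora are proprietary database exports; every pipeline
stage here is therefore exercised on synthetic corpora whose truth is known
by construction.  The centrepiece is :func:`generate_flow_fixture`, which
realizes a :class:`FlowSpec` — a full screening/matching accounting plan —
exactly: how many records fail the direct-funding screen and why, how many
are funded only by non-participating subsidiaries, how the transparency
cohort decomposes into matched / remaining / removed-only authors, how many
disclosure names are planted as perturbed renderings of cohort authors, and
the corresponding-author survey outcome counts.

The packaged default plan (``data/default_flow.yaml``) realizes the audit's
published flow: 779 records, 318 screen exclusions, Sample 1 = 461,
Sample 2 = 389, a 331-study / 907-author cohort, a 218-name disclosure list
with 42 planted correspondences, 152 articles / 527 authors left after
removing matched-author publications, and a 131-respondent survey.

Everything is deterministic given the spec's seed.  Generated names, funding
statements and abstracts are templated synthetic text — no real researcher,
journal or list content is imitated.
"""

from __future__ import annotations

import itertools
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .records import (AuthorRendering, BiblioRecord, CorpusError,
                      DisclosureEntry, EntityDictionary, SurveyOutcome,
                      parse_author, read_entity_dictionary)

__all__ = [
    "FlowSpec", "SyntheticTruth", "load_flow_spec",
    "default_entity_dictionary", "generate_flow_fixture", "perturb_name",
    "generate_topic_corpus", "generate_planted_graph", "write_truth",
]

PERTURBATION_KINDS = frozenset(
    {"initials", "diacritic_fold", "hyphen_split", "order_swap",
     "truncate_given"})


def _data_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("fundingaudit").joinpath("data", name)))


def default_entity_dictionary() -> EntityDictionary:
    return read_entity_dictionary(_data_path("entities.yaml"))


@dataclass
class FlowSpec:
    """Plan for a synthetic audit corpus; validated before generation."""

    n_total: int
    exclusion_plan: dict[str, int]
    subsidiary_plan: int
    cohort_plan: dict[str, int]
    roster_plan: dict[str, int]
    survey_plan: dict[str, int]
    topic_plan: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        def bad(msg: str) -> CorpusError:
            return CorpusError(f"inconsistent flow spec: {msg}")

        for name, plan in [("exclusion_plan", self.exclusion_plan),
                           ("cohort_plan", self.cohort_plan),
                           ("roster_plan", self.roster_plan),
                           ("survey_plan", self.survey_plan)]:
            for k, v in plan.items():
                if v < 0:
                    raise bad(f"{name}[{k}] = {v} is negative")
        n_screened_out = sum(self.exclusion_plan.values())
        sample1 = self.n_total - n_screened_out
        if sample1 <= 0:
            raise bad("screen exclusions exceed the corpus size")
        cohort_excl = (self.subsidiary_plan
                       + self.cohort_plan.get("pre_window", 0)
                       + self.cohort_plan.get("post_window", 0)
                       + self.cohort_plan.get("consortium", 0))
        n_cohort = sample1 - cohort_excl
        if n_cohort <= 0:
            raise bad("cohort exclusions exceed Sample 1")
        rp = self.roster_plan
        n_matched = rp["planted_matches"]
        n_remaining_articles = rp["unmatched_articles"]
        n_removed_articles = n_cohort - n_remaining_articles
        if n_removed_articles < n_matched:
            raise bad("fewer removed articles than planted matches: every "
                      "matched author needs at least one article")
        n_removed_only = (rp["cohort_authors"] - n_matched
                          - rp["unmatched_authors"])
        if n_removed_only < 0:
            raise bad("cohort_authors < planted_matches + unmatched_authors")
        if rp["disclosure_size"] < n_matched:
            raise bad("disclosure list smaller than planted matches")
        if rp["unmatched_corresponding"] > n_remaining_articles:
            raise bad("more distinct corresponding authors than articles")
        if rp["unmatched_authors"] < rp["unmatched_corresponding"]:
            raise bad("corresponding authors exceed remaining author pool")
        if sum(self.survey_plan.values()) != rp["unmatched_corresponding"]:
            raise bad("survey outcome counts must sum to the number of "
                      "surveyed corresponding authors")

    @property
    def n_sample1(self) -> int:
        return self.n_total - sum(self.exclusion_plan.values())

    @property
    def n_sample2(self) -> int:
        return self.n_sample1 - self.subsidiary_plan

    @property
    def n_cohort(self) -> int:
        return (self.n_sample1 - self.subsidiary_plan
                - self.cohort_plan.get("pre_window", 0)
                - self.cohort_plan.get("post_window", 0)
                - self.cohort_plan.get("consortium", 0))


def load_flow_spec(path: str | Path | None = None) -> FlowSpec:
    """Load a flow spec from YAML; defaults to the packaged plan."""
    import yaml

    if path is None:
        path = _data_path("default_flow.yaml")
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    spec = FlowSpec(
        n_total=int(data["n_total"]),
        exclusion_plan={k: int(v) for k, v in data["exclusion_plan"].items()},
        subsidiary_plan=int(data["subsidiary_plan"]),
        cohort_plan={k: int(v) for k, v in data["cohort_plan"].items()},
        roster_plan={k: int(v) for k, v in data["roster_plan"].items()},
        survey_plan={k: int(v) for k, v in data["survey_plan"].items()},
        topic_plan=dict(data.get("topic_plan", {})),
        seed=int(data["seed"]),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# names
# ---------------------------------------------------------------------------

_SURNAME_SYLLABLES = [
    "bar", "bel", "dan", "dor", "fal", "fin", "gar", "gul", "hem", "hol",
    "jan", "jur", "kam", "kos", "lam", "lin", "mor", "mun", "nes", "nor",
    "pol", "rak", "rud", "sal", "tor", "ven", "wal", "yor", "zam", "zel",
]

_GIVEN_PLAIN = [
    "Alan", "Beatriz", "Carla", "Daniel", "Elena", "Frank", "Greta",
    "Henrik", "Ines", "Johan", "Karin", "Laura", "Marco", "Nadia",
    "Oscar", "Paula", "Quentin", "Rosa", "Simon", "Tanja", "Ulric",
    "Vera", "Walter", "Xenia", "Yann", "Zara",
]

_GIVEN_DIACRITIC = [
    "José", "María", "Jürgen", "André", "Renée", "Sofía", "Agnès",
    "Tomás", "Éva", "Çetin", "Ángel", "Lucía",
]


@dataclass(frozen=True)
class _Person:
    canonical_id: str
    surname: str
    given: str

    @property
    def raw(self) -> str:
        return f"{self.surname}, {self.given}" if self.given else self.surname

    def rendering(self, canonical: bool = True) -> AuthorRendering:
        return parse_author(self.raw, canonical_id=self.canonical_id)


def _surname_iter(rng: np.random.Generator) -> Iterable[str]:
    combos = [(i, j, k)
              for i in range(len(_SURNAME_SYLLABLES))
              for j in range(len(_SURNAME_SYLLABLES))
              for k in range(len(_SURNAME_SYLLABLES))]
    order = rng.permutation(len(combos))
    for idx in order:
        i, j, k = combos[idx]
        s = _SURNAME_SYLLABLES[i] + _SURNAME_SYLLABLES[j] + _SURNAME_SYLLABLES[k]
        yield s.capitalize()


def _make_persons(n: int, prefix: str, surnames: Iterable[str],
                  rng: np.random.Generator, hyphen_frac: float = 0.07,
                  diacritic_frac: float = 0.15,
                  middle_frac: float = 0.2) -> list[_Person]:
    persons = []
    it = iter(surnames)
    for i in range(n):
        if rng.random() < hyphen_frac:
            surname = f"{next(it)}-{next(it)}"
        else:
            surname = next(it)
        if rng.random() < diacritic_frac:
            given = _GIVEN_DIACRITIC[int(rng.integers(len(_GIVEN_DIACRITIC)))]
        else:
            given = _GIVEN_PLAIN[int(rng.integers(len(_GIVEN_PLAIN)))]
        if rng.random() < middle_frac:
            given += " " + _GIVEN_PLAIN[int(rng.integers(len(_GIVEN_PLAIN)))]
        persons.append(_Person(f"{prefix}{i:04d}", surname, given))
    return persons


def _fold_text(s: str) -> str:
    s = unicodedata.normalize("NFKD", s)
    return "".join(c for c in s if not unicodedata.combining(c))


def perturb_name(rendering: AuthorRendering, kinds: set[str] | frozenset[str],
                 seed: int = 0) -> AuthorRendering:
    """Re-render a name the way an inconsistent byline would.

    Supported kinds: ``initials`` (given names to initials),
    ``diacritic_fold`` (strip accents), ``hyphen_split`` (hyphenated surname
    to spaced tokens), ``order_swap`` ("Given Surname" order, comma-free),
    ``truncate_given`` (first given name clipped).  The canonical identity
    is preserved; kinds that do not apply to a particular name (no
    diacritics to fold, nothing to truncate) leave it unchanged.
    Deterministic given ``seed``.
    """
    unknown = set(kinds) - PERTURBATION_KINDS
    if unknown:
        raise CorpusError(f"unknown perturbation kinds: {sorted(unknown)}")
    import random

    rnd = random.Random(seed)
    surname = rendering.surname
    given_tokens = rendering.given.split()
    if "diacritic_fold" in kinds:
        surname = _fold_text(surname)
        given_tokens = [_fold_text(t) for t in given_tokens]
    if "truncate_given" in kinds and given_tokens:
        t = given_tokens[0]
        if len(t) > 4:
            cut = rnd.choice([3, 4])
            given_tokens[0] = t[:cut]
    if "initials" in kinds:
        given_tokens = [t[0] + "." for t in given_tokens if t]
    if "hyphen_split" in kinds:
        surname = surname.replace("-", " ")
    given = " ".join(given_tokens)
    if "order_swap" in kinds:
        raw = f"{given} {surname}".strip()
        if "," in raw:
            raw = raw.replace(",", " ")
        rend = parse_author(raw, canonical_id=rendering.canonical_id)
        # comma-free order leaves a multi-token surname partly in the given
        # field; raw is what matters downstream
        return rend
    raw = f"{surname}, {given}" if given else surname
    return parse_author(raw, canonical_id=rendering.canonical_id)


def _render_inconsistently(person: _Person, rng: np.random.Generator
                           ) -> AuthorRendering:
    """Draw a per-publication rendering of a canonical name."""
    u = rng.random()
    has_diacritic = any(ord(c) > 127 for c in person.given + person.surname)
    hyphenated = "-" in person.surname
    kinds: set[str] = set()
    if u < 0.45:
        kinds = set()
    elif u < 0.70:
        kinds = {"initials"}
    elif u < 0.78:
        kinds = {"truncate_given"}
    elif u < 0.85 and has_diacritic:
        kinds = {"diacritic_fold"}
    elif u < 0.90 and hyphenated:
        kinds = {"hyphen_split"}
    elif u < 0.95:
        kinds = {"order_swap"}
    else:
        kinds = {"initials", "diacritic_fold"} if has_diacritic else {"initials"}
    return perturb_name(person.rendering(), kinds,
                        seed=int(rng.integers(2 ** 31)))


def _edit1_neighbourhood_hits(s: str, pool: set[str]) -> bool:
    """True if s is within edit distance 1 of any string in pool."""
    if s in pool:
        return True
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    low = s.lower()
    for i in range(len(low)):
        if low[:i] + low[i + 1:] in pool:                      # deletion
            return True
        for c in alphabet:
            if c != low[i] and low[:i] + c + low[i + 1:] in pool:  # subst
                return True
    for i in range(len(low) + 1):
        for c in alphabet:
            if low[:i] + c + low[i:] in pool:                  # insertion
                return True
    return False


# ---------------------------------------------------------------------------
# funding statements
# ---------------------------------------------------------------------------

_DIRECT_TEMPLATES = [
    "This study was funded by {ent}.",
    "This work was supported by a research grant from {ent}.",
    "The authors acknowledge financial support from {ent}.",
    "This trial was supported by {ent} and by the National Fitness Fund.",
]

_CI_TEMPLATES = [
    "{ini} has received speaking fees from {ent}.",
    "{ini} has served as a consultant to {ent}.",
    "{ini} reports honoraria from {ent} and advisory board membership.",
    "{ini} is an employee of {ent}.",
]

_INDIRECT_TEMPLATES = [
    "This work was supported by a student grant from {ent}.",
    "{ini} received a student grant from {ent} for data collection.",
    "Publication costs were covered via {ent}.",
    "The first author was supported by a travel grant from {ent}.",
]

_OTHER_COLA_TEMPLATES = [
    "This study was funded by {ent}.",
    "This work was supported by a research grant from {ent}.",
]

_INDEXING_TEMPLATES = [
    "This study was supported by the National Dairy Board. Participants "
    "consumed a caffeinated cola beverage.",
    "Funding was provided by the Ministry of Health. The cola condition "
    "was unblinded to participants.",
]

_CONSORTIUM_TEMPLATE = ("This study was conducted by the {name} Research "
                        "Consortium, funded by {ent}.")


def _initials_of(person: _Person) -> str:
    parts = [t[0] for t in person.given.split() if t] + [person.surname[0]]
    return ".".join(parts) + "."


# ---------------------------------------------------------------------------
# topic corpus
# ---------------------------------------------------------------------------

_WORD_SYLLABLES = ["ba", "do", "fu", "ga", "ka", "lo", "mu", "na", "po",
                   "ru", "ta", "vo", "za", "bo", "du", "ha"]


def _topic_vocab(vocab_size: int, rng: np.random.Generator) -> list[str]:
    from .stemming import STOPWORDS, porter_stem

    combos = list(itertools.product(range(len(_WORD_SYLLABLES)), repeat=3))
    order = rng.permutation(len(combos))
    vocab: list[str] = []
    for idx in order:
        i, j, k = combos[idx]
        w = _WORD_SYLLABLES[i] + _WORD_SYLLABLES[j] + _WORD_SYLLABLES[k]
        if w in STOPWORDS or porter_stem(w) != w:
            continue
        vocab.append(w)
        if len(vocab) == vocab_size:
            return vocab
    raise CorpusError("vocabulary request exceeds the synthetic word space")


def generate_topic_corpus(n_docs: int, k_true: int, vocab_size: int,
                          doc_length: int, concentration: float,
                          seed: int) -> tuple[list[str], dict]:
    """Documents from the standard mixture-of-topics generative process.

    Per-document topic weights are symmetric-Dirichlet(``concentration``);
    topic word distributions are uniform over ``k_true`` disjoint vocabulary
    blocks, so topics are separable by construction.  Returns the documents
    (space-joined synthetic stems, all stemmer-fixed points) and a truth
    dict with ``theta`` (n_docs × k), ``phi`` (k × V) and ``vocab``.
    """
    if k_true < 2:
        raise CorpusError("topic corpus needs k_true >= 2")
    if doc_length <= 0:
        raise CorpusError("doc_length must be positive")
    if vocab_size < k_true:
        raise CorpusError("vocab_size must be at least k_true")
    rng = np.random.default_rng(seed)
    vocab = _topic_vocab(vocab_size, rng)
    blocks = np.array_split(np.arange(vocab_size), k_true)
    phi = np.zeros((k_true, vocab_size))
    for k, block in enumerate(blocks):
        phi[k, block] = 1.0 / len(block)
    theta = rng.dirichlet([concentration] * k_true, size=n_docs)
    docs: list[str] = []
    for d in range(n_docs):
        z = rng.choice(k_true, size=doc_length, p=theta[d])
        word_idx = np.empty(doc_length, dtype=int)
        for t in range(k_true):
            mask = z == t
            n_t = int(mask.sum())
            if n_t:
                # phi is uniform over the topic's block by construction
                word_idx[mask] = blocks[t][rng.integers(0, len(blocks[t]),
                                                        size=n_t)]
        docs.append(" ".join(vocab[int(i)] for i in word_idx))
    return docs, {"theta": theta, "phi": phi, "vocab": vocab}


# ---------------------------------------------------------------------------
# planted graphs
# ---------------------------------------------------------------------------

def generate_planted_graph(blocks: Sequence[int], p_in: float, p_out: float,
                           bridge_edges: int = 0, seed: int = 0
                           ) -> tuple[nx.Graph, dict[int, int]]:
    """Stochastic-block-style weighted graph with planted community labels.

    Within-block edges appear with probability ``p_in``, across blocks with
    ``p_out``; ``bridge_edges`` deterministic extra edges join consecutive
    blocks.  Returns the graph (unit weights) and node → block truth labels.
    """
    if any(b <= 0 for b in blocks):
        raise CorpusError("block sizes must be positive")
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise CorpusError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    labels: dict[int, int] = {}
    node = 0
    block_nodes: list[list[int]] = []
    for bi, size in enumerate(blocks):
        nodes = list(range(node, node + size))
        node += size
        block_nodes.append(nodes)
        for n in nodes:
            g.add_node(n)
            labels[n] = bi
    for u in range(node):
        for v in range(u + 1, node):
            p = p_in if labels[u] == labels[v] else p_out
            if p > 0 and rng.random() < p:
                g.add_edge(u, v, weight=1)
    for bi in range(len(blocks) - 1):
        added = 0
        for u in block_nodes[bi]:
            for v in block_nodes[bi + 1]:
                if added >= bridge_edges:
                    break
                if not g.has_edge(u, v):
                    g.add_edge(u, v, weight=1)
                    added += 1
            if added >= bridge_edges:
                break
    return g, labels


# ---------------------------------------------------------------------------
# flow fixture
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground-truth sidecar for a generated corpus."""

    record_category: dict[str, str]            # included | screen reason
    cohort_status: dict[str, str]              # cohort | cohort reason
    funder_group: dict[str, str]
    rendering_identity: dict[tuple[str, int], str]
    persons: dict[str, dict]
    disclosure_identity: list[str | None]
    planted_match_ids: list[str]
    communities: dict[str, str]
    n_components: dict[str, int]
    topic_truth: dict
    n_unique_cohort_authors: int
    remaining_record_ids: list[str]


def _journal_pool(rng: np.random.Generator) -> list[str]:
    adjs = ["Synthetic", "Applied", "Clinical", "European", "International",
            "Annals of", "Archives of", "Current"]
    subjects = ["Nutrition", "Metabolism", "Exercise Science", "Public Health",
                "Dietetics", "Physiology", "Obesity Research",
                "Beverage Studies"]
    pool = [f"{a} {s}" if a.endswith("of") else f"Journal of {a} {s}"
            for a in adjs for s in subjects]
    order = rng.permutation(len(pool))
    return [pool[i] for i in order[:40]]


def generate_flow_fixture(spec: FlowSpec
                          ) -> tuple[list[BiblioRecord], list[DisclosureEntry],
                                     list[SurveyOutcome], SyntheticTruth]:
    """Generate a corpus realizing ``spec`` exactly (see module docstring)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dictionary = default_entity_dictionary()
    by_group: dict[str, list[str]] = {}
    for ent in dictionary.entities:
        by_group.setdefault(ent.group, []).extend(ent.variants)
    journals = _journal_pool(rng)
    surnames = _surname_iter(rng)

    rp = spec.roster_plan
    n_cohort_articles = spec.n_cohort
    n_matched = rp["planted_matches"]
    n_remaining = rp["unmatched_articles"]
    n_removed = n_cohort_articles - n_remaining
    n_removed_only = rp["cohort_authors"] - n_matched - rp["unmatched_authors"]
    n_corr = rp["unmatched_corresponding"]

    cohort_persons = _make_persons(rp["cohort_authors"], "A", surnames, rng)
    perm = rng.permutation(rp["cohort_authors"])
    matched_persons = [cohort_persons[i] for i in perm[:n_matched]]
    remaining_persons = [cohort_persons[i]
                         for i in perm[n_matched:n_matched + rp["unmatched_authors"]]]
    removed_only_persons = [cohort_persons[i]
                            for i in perm[n_matched + rp["unmatched_authors"]:]]
    extra_persons = _make_persons(340, "E", surnames, rng)
    screenfail_persons = _make_persons(380, "S", surnames, rng)

    def pick_variant(groups: Sequence[str]) -> tuple[str, str]:
        weights = [0.6, 0.1, 0.1, 0.1, 0.1][: len(groups)]
        w = np.array(weights) / sum(weights)
        g = groups[int(rng.choice(len(groups), p=w))]
        vs = by_group[g]
        return g, vs[int(rng.integers(len(vs)))]

    participating = ["parent_company", "foundation", "institute_bihw",
                     "north_america", "subsidiary_participating"]

    records: list[BiblioRecord] = []
    record_category: dict[str, str] = {}
    cohort_status: dict[str, str] = {}
    funder_group: dict[str, str] = {}
    rendering_identity: dict[tuple[str, int], str] = {}
    communities: dict[str, str] = {}
    rid_counter = itertools.count(1)

    def new_record(persons_on: Sequence[_Person], year: int,
                   month: int | None, funding_text: str,
                   agency_strings: list[str], category: str,
                   cstat: str | None, group: str,
                   consortium: bool = False,
                   corresponding: int | None = 0) -> BiblioRecord:
        rid = f"R{next(rid_counter):04d}"
        authors = [_render_inconsistently(p, rng) for p in persons_on]
        rec = BiblioRecord(
            record_id=rid, title="", journal=journals[int(rng.integers(40))],
            year=year, month=month, authors=authors,
            corresponding_author_index=corresponding,
            funding_text=funding_text, agency_strings=agency_strings,
            consortium_flag=consortium)
        records.append(rec)
        record_category[rid] = category
        if cstat is not None:
            cohort_status[rid] = cstat
        funder_group[rid] = group
        for i, p in enumerate(persons_on):
            rendering_identity[(rid, i)] = p.canonical_id
        return rec

    def in_window_date() -> tuple[int, int | None]:
        year = 2010 + int(rng.integers(6))
        month = int(rng.integers(1, 13)) if rng.random() < 0.8 else None
        return year, month

    def direct_text(variant: str, group: str) -> tuple[str, list[str]]:
        if group == "institute_bihw":
            text = (f"This study was funded by the {variant}, "
                    f"The Coca-Cola Company.")
        else:
            tpl = _DIRECT_TEMPLATES[int(rng.integers(len(_DIRECT_TEMPLATES)))]
            text = tpl.format(ent=variant)
        canon = next(e.canonical_name for e in dictionary.entities
                     if variant in e.variants)
        agencies = [canon]
        if "National Fitness Fund" in text:
            agencies.append("National Fitness Fund")
        return text, agencies

    # --- cohort articles: remaining (untouched by any match) ----------------
    remaining_ids: list[str] = []
    cluster_size = 8
    new_alloc = np.full(n_remaining, rp["unmatched_authors"] // n_remaining)
    new_alloc[: rp["unmatched_authors"] % n_remaining] += 1
    corr_persons: list[_Person] = []
    pos = 0
    hubs: dict[int, _Person] = {}
    article_authors: list[list[_Person]] = []
    for a in range(n_remaining):
        cluster = a // cluster_size
        fresh = remaining_persons[pos: pos + int(new_alloc[a])]
        pos += int(new_alloc[a])
        authors = list(fresh)
        if cluster not in hubs:
            hubs[cluster] = fresh[0]
        elif hubs[cluster] not in authors:
            authors.append(hubs[cluster])
            if a % 3 == 2 and article_authors:
                # recurring collaboration: repeat a pair so some edges
                # carry weight > 1
                prev = article_authors[-1][0]
                if prev not in authors:
                    authors.append(prev)
        article_authors.append(authors)
    assert pos == rp["unmatched_authors"]
    # corresponding authors: first fresh author of the first n_corr articles;
    # later articles re-use an earlier corresponding author (appended to the
    # byline), creating cross-cluster bridges and the planned overlap
    for a in range(n_remaining):
        if a < n_corr:
            corr_persons.append(article_authors[a][0])
        else:
            reuse = corr_persons[a - n_corr]
            if reuse not in article_authors[a]:
                article_authors[a].append(reuse)
            corr_persons.append(reuse)
    for a in range(n_remaining):
        year, month = in_window_date()
        group, variant = pick_variant(participating)
        text, agencies = direct_text(variant, group)
        corr_idx = article_authors[a].index(corr_persons[a])
        rec = new_record(article_authors[a], year, month, text, agencies,
                         "included", "cohort", group,
                         corresponding=corr_idx)
        remaining_ids.append(rec.record_id)
        for p in article_authors[a]:
            communities.setdefault(p.canonical_id, f"rem-{a // cluster_size}")

    # --- cohort articles: removed (carry >= 1 matched author) --------------
    x_alloc = np.full(n_removed, n_removed_only // n_removed)
    x_alloc[: n_removed_only % n_removed] += 1
    pos = 0
    for j in range(n_removed):
        m = matched_persons[j % n_matched]
        fresh = removed_only_persons[pos: pos + int(x_alloc[j])]
        pos += int(x_alloc[j])
        authors = [m] + list(fresh)
        year, month = in_window_date()
        group, variant = pick_variant(participating)
        text, agencies = direct_text(variant, group)
        new_record(authors, year, month, text, agencies,
                   "included", "cohort", group)
        for p in authors:
            communities.setdefault(p.canonical_id, f"rm-{j % n_matched}")
    assert pos == n_removed_only

    # --- Sample-1 records outside the cohort --------------------------------
    extra_pos = 0
    extra_calls = 0

    def extra_block(n: int) -> list[_Person]:
        # consecutive records share one author so excluded-record groups form
        # small chained components; the chain breaks every sixth record
        nonlocal extra_pos, extra_calls
        take = [extra_persons[(extra_pos + i) % len(extra_persons)]
                for i in range(n)]
        extra_calls += 1
        extra_pos += n if extra_calls % 6 == 0 else max(1, n - 1)
        return take

    for _ in range(spec.subsidiary_plan):
        year, month = in_window_date()
        vs = by_group["subsidiary_nonparticipating"]
        variant = vs[int(rng.integers(len(vs)))]
        text, agencies = direct_text(variant, "subsidiary_nonparticipating")
        new_record(extra_block(2 + int(rng.integers(3))), year, month, text,
                   agencies, "included", "subsidiary_nonparticipating",
                   "subsidiary_nonparticipating")
    for _ in range(spec.cohort_plan.get("pre_window", 0)):
        year = 2008 + int(rng.integers(2))
        month = int(rng.integers(1, 13)) if rng.random() < 0.7 else None
        group, variant = pick_variant(participating)
        text, agencies = direct_text(variant, group)
        new_record(extra_block(2 + int(rng.integers(3))), year, month, text,
                   agencies, "included", "pre_window", group)
    for _ in range(spec.cohort_plan.get("post_window", 0)):
        month = int(rng.integers(1, 7)) if rng.random() < 0.8 else None
        group, variant = pick_variant(participating)
        text, agencies = direct_text(variant, group)
        new_record(extra_block(2 + int(rng.integers(3))), 2016, month, text,
                   agencies, "included", "post_window", group)
    for _ in range(spec.cohort_plan.get("consortium", 0)):
        year, month = in_window_date()
        group, variant = pick_variant(participating)
        if "cola" not in variant.lower():
            group, variant = "parent_company", "The Coca-Cola Company"
        text = _CONSORTIUM_TEMPLATE.format(name="Beverage Health", ent=variant)
        canon = next(e.canonical_name for e in dictionary.entities
                     if variant in e.variants)
        new_record(extra_block(2 + int(rng.integers(3))), year, month, text,
                   [canon], "included", "consortium", group, consortium=True)

    # --- screen-failing records ---------------------------------------------
    sf_pos = 0

    def sf_authors(n: int) -> list[_Person]:
        nonlocal sf_pos
        take = [screenfail_persons[(sf_pos + i) % len(screenfail_persons)]
                for i in range(n)]
        sf_pos += n
        return take

    for reason, count in spec.exclusion_plan.items():
        for _ in range(count):
            persons_on = sf_authors(1 + int(rng.integers(3)))
            year = 2008 + int(rng.integers(9))
            month = int(rng.integers(1, 13)) if rng.random() < 0.6 else None
            ini = _initials_of(persons_on[0])
            if reason == "ci_only":
                vs = by_group["parent_company"]
                variant = vs[int(rng.integers(2))]   # longer, brandful forms
                tpl = _CI_TEMPLATES[int(rng.integers(len(_CI_TEMPLATES)))]
                text = tpl.format(ini=ini, ent=variant)
                agencies: list[str] = []
            elif reason == "indirect":
                vs = by_group["parent_company"]
                variant = vs[int(rng.integers(2))]
                tpl = _INDIRECT_TEMPLATES[int(rng.integers(len(_INDIRECT_TEMPLATES)))]
                text = tpl.format(ini=ini, ent=variant)
                agencies = []
            elif reason == "other_cola":
                vs = by_group["other_cola"]
                variant = vs[int(rng.integers(len(vs)))]
                if "cola" not in variant.lower():
                    variant = "Pepsi-Cola"
                tpl = _OTHER_COLA_TEMPLATES[int(rng.integers(len(_OTHER_COLA_TEMPLATES)))]
                text = tpl.format(ent=variant)
                agencies = [variant]
            elif reason == "indexing_error":
                text = _INDEXING_TEMPLATES[int(rng.integers(len(_INDEXING_TEMPLATES)))]
                agencies = ["The Coca-Cola Company"]
            else:
                raise CorpusError(f"unknown screen exclusion reason {reason!r}")
            new_record(persons_on, year, month, text, agencies, reason,
                       None, "none")

    if len(records) != spec.n_total:
        raise CorpusError("generator bug: record count does not match plan")

    # --- abstracts -----------------------------------------------------------
    tp = spec.topic_plan or {}
    docs, topic_truth = generate_topic_corpus(
        n_docs=spec.n_total,
        k_true=int(tp.get("k", 6)),
        vocab_size=int(tp.get("vocab_size", 240)),
        doc_length=int(tp.get("doc_length", 80)),
        concentration=float(tp.get("concentration", 0.2)),
        seed=int(rng.integers(2 ** 31)))
    vocab = topic_truth["vocab"]
    for i, rec in enumerate(records):
        rec.abstract = docs[i]
        w1, w2 = vocab[int(rng.integers(len(vocab)))], vocab[int(rng.integers(len(vocab)))]
        rec.title = f"Effects of {w1} on {w2}"

    # --- disclosure list -----------------------------------------------------
    sources = ["USA", "UK", "France", "Germany", "Australia"]
    entries: list[DisclosureEntry] = []
    disclosure_identity: list[str | None] = []
    planted_kind_menu = [set(), {"initials"}, {"diacritic_fold"},
                         {"hyphen_split"}, {"order_swap"},
                         {"initials", "diacritic_fold"}]
    for i, person in enumerate(matched_persons):
        kinds = planted_kind_menu[int(rng.integers(len(planted_kind_menu)))]
        rend = perturb_name(person.rendering(), kinds,
                            seed=int(rng.integers(2 ** 31)))
        entries.append(DisclosureEntry(rend.raw, sources[i % len(sources)],
                                       "researcher"))
        disclosure_identity.append(person.canonical_id)
    cohort_anchor_pool = set()
    for p in cohort_persons:
        for tok in _fold_text(p.surname).lower().replace("-", " ").split():
            cohort_anchor_pool.add(tok)
    n_distract = rp["disclosure_size"] - n_matched
    made = 0
    for surname in surnames:
        if made == n_distract:
            break
        if _edit1_neighbourhood_hits(surname.lower(), cohort_anchor_pool):
            continue
        given = _GIVEN_PLAIN[int(rng.integers(len(_GIVEN_PLAIN)))]
        kind = "researcher" if rng.random() < 0.7 else "non-academic expert"
        entries.append(DisclosureEntry(f"{surname}, {given}",
                                       sources[int(rng.integers(len(sources)))],
                                       kind))
        disclosure_identity.append(None)
        made += 1
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    disclosure_identity = [disclosure_identity[i] for i in order]

    # --- survey outcomes -----------------------------------------------------
    distinct_corr = list(dict.fromkeys(corr_persons))[:n_corr]
    assert len(distinct_corr) == n_corr
    corr_order = rng.permutation(n_corr)
    outcomes: list[SurveyOutcome] = []
    labels = (["confirmed"] * spec.survey_plan.get("confirmed", 0)
              + ["denied"] * spec.survey_plan.get("denied", 0)
              + ["no_reply"] * spec.survey_plan.get("no_reply", 0)
              + ["invalid_address"] * spec.survey_plan.get("invalid_address", 0))
    denier_quota = 5
    for pos_i, lab in enumerate(labels):
        person = distinct_corr[int(corr_order[pos_i])]
        named: tuple[str, ...] = ()
        if lab == "denied" and denier_quota > 0:
            art = next(aa for aa in article_authors if person in aa)
            others = [p for p in art if p is not person]
            if others:
                named = (others[0].raw,)
                denier_quota -= 1
        outcomes.append(SurveyOutcome(person.raw, lab, named))

    # --- shuffle corpus order (decisions are record-local) -------------------
    rec_order = rng.permutation(len(records))
    records = [records[i] for i in rec_order]

    # --- truth sidecar -------------------------------------------------------
    persons_meta: dict[str, dict] = {}
    for p, role in itertools.chain(
            ((q, "matched") for q in matched_persons),
            ((q, "remaining") for q in remaining_persons),
            ((q, "removed_only") for q in removed_only_persons),
            ((q, "extra") for q in extra_persons),
            ((q, "screenfail") for q in screenfail_persons)):
        persons_meta[p.canonical_id] = {
            "surname": p.surname, "given": p.given, "role": role,
            "raw": p.raw}

    def truth_graph(record_ids: set[str]) -> nx.Graph:
        g = nx.Graph()
        for rec in records:
            if rec.record_id not in record_ids:
                continue
            ids = sorted({rendering_identity[(rec.record_id, i)]
                          for i in range(len(rec.authors))})
            g.add_nodes_from(ids)
            for a, b in itertools.combinations(ids, 2):
                g.add_edge(a, b)
        return g

    sample1_ids = {rid for rid, cat in record_category.items()
                   if cat == "included"}
    cohort_ids = {rid for rid, st in cohort_status.items() if st == "cohort"}
    n_components = {
        "sample1": nx.number_connected_components(truth_graph(sample1_ids)),
        "cohort": nx.number_connected_components(truth_graph(cohort_ids)),
    }

    truth = SyntheticTruth(
        record_category=record_category,
        cohort_status=cohort_status,
        funder_group=funder_group,
        rendering_identity=rendering_identity,
        persons=persons_meta,
        disclosure_identity=disclosure_identity,
        planted_match_ids=[p.canonical_id for p in matched_persons],
        communities=communities,
        n_components=n_components,
        topic_truth=topic_truth,
        n_unique_cohort_authors=rp["cohort_authors"],
        remaining_record_ids=remaining_ids,
    )
    return records, entries, outcomes, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Truth sidecar as JSONL: one object per truth table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"table": "record_category",
                             "data": truth.record_category}) + "\n")
        fh.write(json.dumps({"table": "cohort_status",
                             "data": truth.cohort_status}) + "\n")
        fh.write(json.dumps({
            "table": "rendering_identity",
            "data": {f"{rid}:{idx}": cid
                     for (rid, idx), cid in truth.rendering_identity.items()},
        }) + "\n")
        fh.write(json.dumps({"table": "planted_match_ids",
                             "data": truth.planted_match_ids}) + "\n")
        fh.write(json.dumps({"table": "disclosure_identity",
                             "data": truth.disclosure_identity}) + "\n")
        fh.write(json.dumps({"table": "n_components",
                             "data": truth.n_components}) + "\n")
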