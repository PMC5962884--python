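# Methods

## The audit, as a computable procedure

The audit asks whether a funder's published transparency lists cover the
researchers whose publications acknowledge its money. Because the original
evidence base is a proprietary bibliographic-database export, the package
pins every judgement the original workflow made by hand into explicit,
configurable rules, and validates them on synthetic corpora whose ground
truth is planted by construction.

### Screening rules

A record enters the funded set iff at least one *brand* funder entity is
mentioned in a **direct-funding context** in its funding-acknowledgement
text. Mentions are found by longest-variant-first, non-overlapping,
case-insensitive matching against an entity dictionary (canonical name,
printed variants, brand group); both the free-text statement and the
database-parsed agency strings are scanned, with the source recorded.

"Direct-funding context" is operationalized at sentence granularity:
a sentence must contain a direct cue (*funded by*, *supported by*,
*grant from*, *financial support from*, …) and no indirect cue (*student
grant*, *travel grant*, *via*, …). Sentences with competing-interest cues
(*consultant*, *speaking*, *honoraria*, *advisory*, *employee*) mark a
relationship, not funding. Excluded records receive exactly one reason
code, assigned in the fixed precedence `ci_only > indirect > other_cola >
indexing_error` (a record with several defects carries its primary one).
The `indexing_error` class covers records whose agency table credits the
brand although the statement text does not support direct funding.
Cue lists are config-exposed; the defaults are co-designed with the
synthetic statement templates, which is exactly the calibration the rules
can claim — the suite demonstrates perfect agreement with planted truth on
generated statements, not on free-form prose.

The cohort filter takes the publication window **January 2010 – December
2015 inclusive**; records without a month are judged on year alone.
Consortium-authored records are excluded as indirectly funded. Where a
statement names investigators, non-investigator authors are dropped
individually; where it names none (the overwhelmingly common case) all
authors are retained — the conservative reading.

Every stage writes `ScreeningDecision`s into a ledger whose conservation
invariant (input = output + excluded; reason tallies sum to the excluded
count) is asserted on rendering. Decisions are record-local, so corpus
order is irrelevant, and re-screening a stage's output excludes nothing.

### Name disambiguation and matching

A rendering is folded to a `NameKey`: NFKD diacritic stripping, lowercase,
punctuation to spaces, hyphenated surnames split, "Given Surname" and
"Surname, Given" orders unified. Renderings cluster into canonical persons
when their surname *anchors* (last surname token) agree and the remaining
tokens admit a one-to-one pairing under equality, initial-expansion
(`j` ~ `jurgen`) or truncation (`jurg` ~ `jurgen`, prefix length ≥ 3).
The rule absorbs the rendering variation bibliographic databases actually
produce while never merging two spelled-out distinct given names. Its known
ambiguity — same surname, same first initial, initial-only rendering — is
inherent to string-based disambiguation and documented rather than hidden.

Matching against the disclosure list is one-to-one on canonical persons:
exact folded-key equality first, then approximate candidates that pass the
same anchor gate, scored by normalized Levenshtein similarity on their
aligned token pairs (compatible pairs score 1; token pairs differing by a
single edit at length ≥ 4 score their edit similarity). Assignment is
greedy highest-score-first with lexicographic tie-breaking. Defaults:
auto-accept ≥ 0.90, a 0.80–0.90 `needs_review` band that stands in for the
original manual verification (excluded from automatic counts unless
promoted), rejected below 0.80.

Coverage percentages are reported to one decimal as 100·matched/list-size
and 100·matched/roster-size. Survey percentages are integer-rounded
(half-up). The package computes exact values and does not emulate the
occasionally inconsistent roundings a manual workflow can produce.

### Survey adjustments

Corresponding-author survey outcomes adjust the unacknowledged set:
a **denier**'s name is removed (any primary grant recipients they name are
kept); a **confirmer** accounts for each of their publications, removing
all co-author names on those records; records left with no unaccounted
author are dropped. The adjusted figures depend on the overlap structure of
the surviving articles and are reported as computed, not pinned to any
external value.

### Network analysis

The co-authorship graph joins two canonical authors with weight equal to
their number of shared publications. Degree centrality is the weighted
degree. Betweenness (node and edge) uses shortest paths on the
**unweighted** topology by default — co-publication counts are tie
strengths, not distances — with fractional attribution across equally short
paths; a weighted-distance mode (distance = 1/weight) is available.
Community detection is the divisive edge-betweenness algorithm: remove the
highest-betweenness edge, recompute, repeat; the returned partition is the
component structure of maximal weighted modularity along the removal
sequence (the initial component partition is a candidate, so quality is
never negative). Determinism: among tied edges the lexicographically
smallest (sorted endpoint keys) is removed. The betweenness implementation
is verified against an exhaustive shortest-path-enumeration oracle on all
random connected graphs up to 8 nodes.

### Topic model

Abstracts are lowercased, stripped of punctuation and digits, stopworded
(pinned ~130-word list) and stemmed with a full Porter implementation, then
fitted with the standard mixture-of-topics model by collapsed Gibbs
sampling (own numba kernel; posterior means averaged over every 10th
post-burn-in sweep; deterministic given the seed). Defaults: k = 20 for
real corpora, symmetric document concentration **α = 1/k**, topic
concentration β = 0.01, 2000 sweeps with 500 burn-in. α = 1/k rather than
the folklore 50/k: with ~100-token abstracts, the posterior-mean shrinkage
(n_dk+α)/(n_d+Kα) under α = 50/k pulls near-single-topic documents ~30 %
toward uniform, which both distorts the dominance-ratio statistic the audit
reports and makes planted near-one-hot document weights unrecoverable; a
weakly informative prior preserves them. Reporting follows the audit's
conventions: each abstract is assigned its most probable topic, and the
dominance ratio (top weight / second weight, ties to the lowest topic id at
ratio 1) is averaged per topic.

## The synthetic generator: what it emulates, what it does not

`generate_flow_fixture` realizes a `FlowSpec` exactly. The packaged plan
(`data/default_flow.yaml`, fixed seed) encodes the audit's published
accounting: 779 records of which 318 fail the direct-funding screen
(the per-reason split 200/60/30/28 is fixed by the plan — the published
flow pins only the total), Sample 1 = 461, 72 records funded only by
non-participating subsidiaries (Sample 2 = 389), cohort exclusions
72 + 30 + 18 + 10 = 130 leaving 331 studies by 907 authors, a 218-name
disclosure list with 42 planted correspondences (perturbed renderings of
cohort authors), 152 articles / 527 authors untouched by any match with
exactly 131 distinct corresponding authors, and survey outcomes
14/29/68/20. The published accounting itself subtracts inconsistently
(138 exclusions reported against a 331-study cohort); the plan follows the
operative author-side figures (907/42/527/152/176), which are mutually
consistent.

Emulated features of real data: funder-entity variants and confounders in
templated English statements (competing-interest-only phrasing, student
grants, other same-name brands, indexing errors whose free text lacks the
brand); per-publication inconsistent author renderings (initials,
diacritic folding, hyphen splitting, order swaps, truncation); disclosure
distractor names whose surnames are verified ≥ 2 edits from every cohort
surname token; block-structured co-authorship (hub-linked article clusters,
cross-cluster bridges, recurring pairs with edge weight > 1); and
mixture-of-topics abstracts over a synthetic stemmer-fixed vocabulary.

Not emulated: free-form funding prose beyond the templates, real names,
journals or list content, affiliation data, and within-cohort surname
collisions (every synthetic person has a unique surname, so disambiguation
on the fixture is exact by design). Passing fixture tests therefore
demonstrates that the *rules are implemented and composed correctly*, not
that the cue lists or thresholds would achieve any particular accuracy on
real statements — which is why every threshold is config-exposed and every
borderline match is surfaced for review.

## Numerical and design choices

- Tie-breaks are lexicographic everywhere (edge removal, match assignment,
  dominant-topic ties) — determinism was preferred wherever the procedure
  is otherwise silent.
- Edge-betweenness ties are compared with a relative 1e-9 tolerance before
  tie-breaking.
- Probability tables are posterior means; row normalization is asserted to
  1e-9.
- An edgeless graph partitions into singletons with quality 0; an empty
  corpus yields an all-zero ledger; empty-after-preprocessing documents are
  dropped with their ids logged.
- Problem sizes in tests and drivers: topic recovery runs at n = 200–400
  documents (k = 2–3) and the fixture's abstracts carry 6 planted topics
  fitted with 600 sweeps in the drivers; planted-graph recovery uses two
  20-node blocks. These sizes give stable recovery statistics while keeping
  a full reproduction run in the minutes range on one core.
- Community detection inside the pipeline runs per connected component and
  skips components above a configurable edge cap (default 2000), reporting
  them as single communities; the divisive algorithm's cost is impractical
  beyond that, and the audit's corpora split into many small components.

## Known limitations

- The direct-funding classifier is a cue-phrase system; it does not parse
  syntax and will misread statements whose funding and competing-interest
  clauses share a sentence in adversarial ways.
- String-based disambiguation cannot separate same-surname/same-initial
  people, and the one-to-one assignment resolves genuine ambiguity
  greedily.
- The divisive community algorithm is quadratic-to-cubic in component size;
  use the Leiden/Louvain family for large real graphs (out of scope here).
- Survey-adjusted totals depend on article overlap and are not invariant
  summary statistics; they are reported but not used as acceptance
  anchors.
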