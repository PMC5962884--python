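"""Shared fixtures: the packaged flow fixture is generated once per session
and screened/matched once, since many tests assert against the same corpus."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from fundingaudit import matching, names, screening, synth
from fundingaudit.records import BiblioRecord, parse_author


@dataclass
class FixtureRun:
    spec: synth.FlowSpec
    records: list
    disclosure: list
    survey: list
    truth: synth.SyntheticTruth
    prefiltered: list
    screen_decisions: list
    mention_map: dict
    sample1: list
    sample2: list
    cohort: screening.CohortResult
    clusters: list
    assignment: dict
    match_results: list
    accepted: list
    remaining: list
    remaining_clusters: list


@pytest.fixture(scope="session")
def fixture_run() -> FixtureRun:
    spec = synth.load_flow_spec()
    records, disclosure, survey, truth = synth.generate_flow_fixture(spec)
    dictionary = synth.default_entity_dictionary()
    prefiltered, _ = screening.prefilter_by_substring(records, "cola")
    _, decisions, mention_map = screening.screen_corpus(prefiltered, dictionary)
    sample1 = screening.build_sample1(prefiltered, decisions)
    sample2, _ = screening.build_sample2(sample1, mention_map)
    cohort = screening.build_transparency_cohort(sample1, mention_map)
    clusters, assignment = names.cluster_records(cohort.records)
    results = matching.match_author_lists(clusters, disclosure)
    accepted = matching.accepted_matches(results)
    remaining, remaining_clusters = matching.remove_matched_publications(
        cohort.records, results, clusters, assignment)
    return FixtureRun(spec, records, disclosure, survey, truth, prefiltered,
                      decisions, mention_map, sample1, sample2, cohort,
                      clusters, assignment, results, accepted, remaining,
                      remaining_clusters)


@pytest.fixture()
def small_spec() -> synth.FlowSpec:
    """A miniature, internally consistent flow plan for fast pipeline tests."""
    spec = synth.FlowSpec(
        n_total=40,
        exclusion_plan={"ci_only": 4, "indirect": 2, "other_cola": 2,
                        "indexing_error": 2},
        subsidiary_plan=4,
        cohort_plan={"pre_window": 2, "post_window": 2, "consortium": 2,
                     "non_pi": 0},
        roster_plan={"cohort_authors": 60, "planted_matches": 4,
                     "disclosure_size": 10, "unmatched_articles": 12,
                     "unmatched_authors": 40, "unmatched_corresponding": 10},
        survey_plan={"confirmed": 2, "denied": 3, "no_reply": 4,
                     "invalid_address": 1},
        topic_plan={"k": 3, "vocab_size": 60, "doc_length": 40,
                    "concentration": 0.2},
        seed=424242,
    )
    spec.validate()
    return spec


def make_record(record_id: str = "R1", authors: list[str] | None = None,
                **kwargs) -> BiblioRecord:
    defaults = dict(title="t", journal="j", year=2012)
    defaults.update(kwargs)
    return BiblioRecord(
        record_id=record_id,
        authors=[parse_author(a) for a in (authors or ["Doe, Jane"])],
        **defaults)
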