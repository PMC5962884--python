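"""Disclosure matching, coverage statistics, removal and survey adjustment."""

import pytest

from fundingaudit import matching, names
from fundingaudit.matching import (MatchConfig, apply_survey_adjustments,
                                   coverage_metrics, levenshtein,
                                   match_author_lists,
                                   remove_matched_publications, similarity,
                                   survey_tally)
from fundingaudit.names import dedupe_authors
from fundingaudit.records import (CorpusError, DisclosureEntry, SurveyOutcome,
                                  parse_author)

from conftest import make_record


def _clusters(*raws):
    return dedupe_authors([parse_author(r) for r in raws])


def test_levenshtein_and_similarity():
    assert levenshtein("kitten", "sitting") == 3
    assert similarity("abc", "abc") == 1.0
    assert similarity("", "") == 1.0


def test_exact_match_scores_one():
    clusters = _clusters("Hemdor, Paula")
    entries = [DisclosureEntry("Hemdor, Paula")]
    (res,) = match_author_lists(clusters, entries)
    assert res.match_type == "exact" and res.score == 1.0
    assert res.review_status == "auto_accepted"


def test_initials_rendering_matches():
    clusters = _clusters("Hemdor, Paula")
    entries = [DisclosureEntry("Hemdor, P.")]
    (res,) = match_author_lists(clusters, entries)
    assert res.review_status == "auto_accepted"
    assert res.match_type == "approximate"


def test_surname_gate_blocks_different_surnames():
    clusters = _clusters("Hemdor, Paula")
    entries = [DisclosureEntry("Hemdar, Paula")]   # 1 edit away: gate fails
    results = match_author_lists(clusters, entries)
    assert matching.accepted_matches(results) == []


def test_one_to_one_on_persons():
    clusters = _clusters("Hemdor, Paula", "Hemdor, Paulina")
    entries = [DisclosureEntry("Hemdor, Paula", "USA"),
               DisclosureEntry("Hemdor, Paula", "UK")]   # same person twice
    results = match_author_lists(clusters, entries)
    acc = matching.accepted_matches(results)
    assert len(acc) == 1


def test_threshold_monotonicity(fixture_run):
    counts = []
    for thr in (0.80, 0.85, 0.90, 0.95, 1.0):
        cfg = MatchConfig(auto_accept=thr, review_low=0.80)
        res = match_author_lists(fixture_run.clusters, fixture_run.disclosure,
                                 cfg)
        counts.append(len(matching.accepted_matches(res, cfg)))
    assert counts == sorted(counts, reverse=True)


def test_planted_recovery_exact_no_false_positives(fixture_run):
    planted = set(fixture_run.truth.planted_match_ids)
    matched_ids = set()
    for m in fixture_run.accepted:
        cluster = fixture_run.clusters[m.cluster_index]
        ids = {r.canonical_id for r in cluster.renderings}
        assert len(ids) == 1
        matched_ids |= ids
    assert matched_ids == planted


def test_coverage_metrics_counts_and_bounds(fixture_run):
    cov = coverage_metrics(fixture_run.match_results, fixture_run.clusters,
                           fixture_run.disclosure)
    assert cov.n_matched <= min(cov.n_cohort_authors, cov.n_disclosure_names)
    assert cov.pct_of_cohort == round(100 * cov.n_matched
                                      / cov.n_cohort_authors, 1)
    assert cov.pct_of_disclosure == round(100 * cov.n_matched
                                          / cov.n_disclosure_names, 1)
    assert len(cov.unmatched_disclosure_names) == \
        cov.n_disclosure_names - cov.n_matched


def test_zero_matches_coverage():
    clusters = _clusters("Hemdor, Paula")
    entries = [DisclosureEntry("Walden, Karin")]
    results = match_author_lists(clusters, entries)
    cov = coverage_metrics(results, clusters, entries)
    assert cov.n_matched == 0
    assert cov.pct_of_cohort == 0.0 and cov.pct_of_disclosure == 0.0


def test_empty_cohort_fatal():
    with pytest.raises(CorpusError):
        match_author_lists([], [DisclosureEntry("X, Y")])


def test_removal_conserves_articles(fixture_run):
    removed = len(fixture_run.cohort.records) - len(fixture_run.remaining)
    assert removed + len(fixture_run.remaining) == \
        len(fixture_run.cohort.records)
    matched = {m.cluster_index for m in fixture_run.accepted}
    for rec in fixture_run.remaining:
        rec_clusters = {fixture_run.assignment[(rec.record_id, i)]
                        for i in range(len(rec.authors))}
        assert not rec_clusters & matched


def test_removal_identity_without_matches():
    records = [make_record("R1", ["Hemdor, Paula"])]
    clusters, assignment = names.cluster_records(records)
    remaining, rem_clusters = remove_matched_publications(
        records, [], clusters, assignment)
    assert remaining == records and len(rem_clusters) == 1


def test_removal_of_sole_authored_matched_record():
    records = [make_record("R1", ["Hemdor, Paula"])]
    clusters, assignment = names.cluster_records(records)
    entries = [DisclosureEntry("Hemdor, Paula")]
    results = match_author_lists(clusters, entries)
    remaining, rem_clusters = remove_matched_publications(
        records, results, clusters, assignment)
    assert remaining == [] and rem_clusters == []


class TestSurvey:
    def test_tally_rounding(self):
        outcomes = ([SurveyOutcome(f"a{i}", "confirmed") for i in range(14)]
                    + [SurveyOutcome(f"d{i}", "denied") for i in range(29)]
                    + [SurveyOutcome(f"n{i}", "no_reply") for i in range(68)]
                    + [SurveyOutcome(f"x{i}", "invalid_address")
                       for i in range(20)])
        tally = survey_tally(outcomes)
        assert tally["confirmed"] == {"count": 14, "pct": 11}
        assert tally["denied"] == {"count": 29, "pct": 22}
        assert tally["total"]["count"] == 131

    def test_single_category_is_100pct(self):
        tally = survey_tally([SurveyOutcome("a", "no_reply")] * 7)
        assert tally["no_reply"]["pct"] == 100

    def test_no_outcomes_fatal(self):
        with pytest.raises(CorpusError):
            survey_tally([])

    def test_no_reply_changes_nothing(self):
        records = [make_record("R1", ["Hemdor, Paula"],
                               corresponding_author_index=0)]
        clusters, assignment = names.cluster_records(records)
        adj_clusters, adj_records, problems = apply_survey_adjustments(
            records, clusters, [SurveyOutcome("Hemdor, Paula", "no_reply")],
            assignment, clusters)
        assert len(adj_clusters) == 1 and adj_records == records
        assert problems == []

    def test_denier_sole_author_record_dropped(self):
        records = [make_record("R1", ["Hemdor, Paula"],
                               corresponding_author_index=0)]
        clusters, assignment = names.cluster_records(records)
        adj_clusters, adj_records, _ = apply_survey_adjustments(
            records, clusters, [SurveyOutcome("Hemdor, Paula", "denied")],
            assignment, clusters)
        assert adj_clusters == [] and adj_records == []

    def test_denier_with_named_recipient_keeps_recipient(self):
        records = [make_record("R1", ["Hemdor, Paula", "Walden, Karin"],
                               corresponding_author_index=0)]
        clusters, assignment = names.cluster_records(records)
        adj_clusters, adj_records, _ = apply_survey_adjustments(
            records, clusters,
            [SurveyOutcome("Hemdor, Paula", "denied", ("Walden, Karin",))],
            assignment, clusters)
        keys = {c.key.anchor for c in adj_clusters}
        assert keys == {"walden"}
        assert adj_records == records

    def test_confirmer_removes_coauthors(self):
        records = [make_record("R1", ["Hemdor, Paula", "Walden, Karin"],
                               corresponding_author_index=0),
                   make_record("R2", ["Dorlin, Vera"],
                               corresponding_author_index=0)]
        clusters, assignment = names.cluster_records(records)
        adj_clusters, adj_records, _ = apply_survey_adjustments(
            records, clusters, [SurveyOutcome("Hemdor, Paula", "confirmed")],
            assignment, clusters)
        keys = {c.key.anchor for c in adj_clusters}
        assert keys == {"dorlin"}
        assert [r.record_id for r in adj_records] == ["R2"]

    def test_unknown_author_reported_not_fatal(self):
        records = [make_record("R1", ["Hemdor, Paula"],
                               corresponding_author_index=0)]
        clusters, assignment = names.cluster_records(records)
        _, _, problems = apply_survey_adjustments(
            records, clusters, [SurveyOutcome("Nobody, At", "denied")],
            assignment, clusters)
        assert len(problems) == 1
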