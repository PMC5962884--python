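"""Screening cascade: mentions, direct-funding rules, samples, ledger."""

import pytest

from fundingaudit import screening
from fundingaudit.records import CorpusError
from fundingaudit.screening import (PrismaLedger, build_sample2,
                                    build_transparency_cohort,
                                    classify_direct_funding,
                                    detect_funder_mentions,
                                    prefilter_by_substring, prisma_summary,
                                    screen_corpus)
from fundingaudit.synth import default_entity_dictionary

from conftest import make_record

DICT = default_entity_dictionary()


def _classify(funding_text, agency_strings=(), **kw):
    rec = make_record("R1", funding_text=funding_text,
                      agency_strings=list(agency_strings), **kw)
    return classify_direct_funding(rec, detect_funder_mentions(rec, DICT))


class TestPrefilter:
    def test_needle_hit_kept(self):
        recs = [make_record("R1", funding_text="Supported by Coca-Cola"),
                make_record("R2", funding_text=""),
                make_record("R3", funding_text="Pepsi-Cola supported this")]
        kept, decisions = prefilter_by_substring(recs, "cola")
        assert [r.record_id for r in kept] == ["R1", "R3"]
        assert [d.included for d in decisions] == [True, False, True]

    def test_empty_needle_fatal(self):
        with pytest.raises(CorpusError):
            prefilter_by_substring([], "")


class TestMentionDetection:
    def test_affiliate_variant(self):
        rec = make_record("R1", funding_text=(
            "funded by the Beverage Institute of Health and Wellness"))
        mentions = detect_funder_mentions(rec, DICT)
        assert len(mentions) == 1
        assert mentions[0].entity_group == "institute_bihw"

    def test_empty_texts_no_mentions(self):
        rec = make_record("R1")
        assert detect_funder_mentions(rec, DICT) == []

    def test_other_cola_brand(self):
        rec = make_record("R1", funding_text="Pepsi-Cola provided funds")
        mentions = detect_funder_mentions(rec, DICT)
        assert [m.entity_group for m in mentions] == ["other_cola"]

    def test_longest_variant_wins_no_overlap(self):
        rec = make_record("R1",
                          funding_text="funded by The Coca-Cola Company")
        mentions = detect_funder_mentions(rec, DICT)
        assert len(mentions) == 1
        assert mentions[0].variant == "The Coca-Cola Company"

    def test_subsidiary_not_shadowed_by_parent_variant(self):
        rec = make_record("R1", funding_text="funded by Coca-Cola Brasil")
        mentions = detect_funder_mentions(rec, DICT)
        assert mentions[0].entity_group == "subsidiary_nonparticipating"

    def test_agency_strings_scanned_with_source(self):
        rec = make_record("R1", agency_strings=["The Coca-Cola Company"])
        mentions = detect_funder_mentions(rec, DICT)
        assert mentions[0].source == "agency_strings"


class TestDirectFundingRules:
    def test_competing_interest_only(self):
        d = _classify("J.S. has received speaking fees from "
                      "The Coca-Cola Company.")
        assert not d.included and d.reason_code == "ci_only"

    def test_indirect_student_grant(self):
        d = _classify("This work was supported by a student grant from "
                      "Coca-Cola.")
        assert not d.included and d.reason_code == "indirect"

    def test_other_cola(self):
        d = _classify("This study was funded by Pepsi-Cola.",
                      ["Pepsi-Cola"])
        assert not d.included and d.reason_code == "other_cola"

    def test_indexing_error(self):
        d = _classify("This study was supported by the National Dairy "
                      "Board. A cola beverage was the comparator.",
                      ["Coca-Cola"])
        assert not d.included and d.reason_code == "indexing_error"

    def test_direct_funding_included(self):
        d = _classify("This study was funded by The Coca-Cola Company.",
                      ["The Coca-Cola Company"])
        assert d.included

    def test_ci_precedes_indirect(self):
        d = _classify("A.B. has consulted for Coca-Cola. "
                      "C.D. held a student grant from Coca-Cola.")
        assert d.reason_code == "ci_only"

    def test_direct_in_one_sentence_overrides_ci_in_another(self):
        d = _classify("This study was funded by Coca-Cola. "
                      "J.S. has consulted for Coca-Cola.")
        assert d.included


class TestSamplesAndCohort:
    def test_sample2_any_participating_mention_suffices(self):
        recs = [
            make_record("R1", funding_text=(
                "This study was funded by The Coca-Cola Company and "
                "by Coca-Cola Brasil.")),
            make_record("R2",
                        funding_text="This study was funded by Coca-Cola "
                                     "Brasil."),
        ]
        kept, decisions, mm = screen_corpus(recs, DICT)
        assert len(kept) == 2
        s2, s2_dec = build_sample2(kept, mm)
        assert [r.record_id for r in s2] == ["R1"]
        assert s2_dec[1].reason_code == "subsidiary_nonparticipating"

    def test_cohort_window_and_consortium(self):
        base = dict(funding_text="This study was funded by Coca-Cola.")
        recs = [make_record("R1", year=2009, **base),
                make_record("R2", year=2016, month=3, **base),
                make_record("R3", year=2012, consortium_flag=True, **base),
                make_record("R4", year=2012, **base),
                make_record("R5", year=2010, month=1, **base)]
        kept, decisions, mm = screen_corpus(recs, DICT)
        cohort = build_transparency_cohort(kept, mm)
        reasons = {d.record_id: d.reason_code for d in cohort.decisions}
        assert reasons["R1"] == "pre_window"
        assert reasons["R2"] == "post_window"
        assert reasons["R3"] == "consortium"
        assert {r.record_id for r in cohort.records} == {"R4", "R5"}

    def test_missing_month_judged_on_year_alone(self):
        rec = make_record("R1", year=2015, month=None,
                          funding_text="This study was funded by Coca-Cola.")
        kept, _, mm = screen_corpus([rec], DICT)
        cohort = build_transparency_cohort(kept, mm)
        assert len(cohort.records) == 1

    def test_non_investigator_authors_dropped_when_named(self):
        rec = make_record("R1", ["Hemdor, Paula", "Walden, Karin"],
                          funding_text="This study was funded by Coca-Cola.",
                          pi_names=["Hemdor, P."])
        kept, _, mm = screen_corpus([rec], DICT)
        cohort = build_transparency_cohort(kept, mm)
        assert cohort.retained_authors["R1"] == [0]

    def test_all_authors_retained_without_pi_information(self):
        rec = make_record("R1", ["Hemdor, Paula", "Walden, Karin"],
                          funding_text="This study was funded by Coca-Cola.")
        kept, _, mm = screen_corpus([rec], DICT)
        cohort = build_transparency_cohort(kept, mm)
        assert cohort.retained_authors["R1"] == [0, 1]


class TestLedgerProperties:
    def test_conservation_and_summary(self, fixture_run):
        ledger = PrismaLedger()
        pre, pre_dec = prefilter_by_substring(fixture_run.records, "cola")
        ledger.add_stage("substring_prefilter", pre_dec)
        ledger.add_stage("direct_funding_screen", fixture_run.screen_decisions)
        table = prisma_summary(ledger)
        screen_row = table[table.stage == "direct_funding_screen"].iloc[0]
        assert (screen_row["input"], screen_row["output"],
                screen_row["excluded"]) == (779, 461, 318)
        for _, row in table.iterrows():
            assert row["input"] == row["output"] + row["excluded"]

    def test_empty_corpus_all_zero(self):
        ledger = PrismaLedger()
        ledger.add_stage("substring_prefilter", [])
        table = prisma_summary(ledger)
        assert (table[["input", "output", "excluded"]].to_numpy() == 0).all()

    def test_decisions_are_record_local(self):
        recs = [make_record(f"R{i}", funding_text=t) for i, t in enumerate([
            "This study was funded by Coca-Cola.",
            "A.B. has consulted for Coca-Cola.",
            "This study was funded by Pepsi-Cola."])]
        _, fwd, _ = screen_corpus(recs, DICT)
        _, rev, _ = screen_corpus(recs[::-1], DICT)
        assert {d.record_id: d.reason_code for d in fwd} == \
            {d.record_id: d.reason_code for d in rev}

    def test_screen_is_idempotent_on_its_own_output(self, fixture_run):
        again, decisions, _ = screen_corpus(fixture_run.sample1, DICT)
        assert len(again) == len(fixture_run.sample1)
        assert all(d.included for d in decisions)


def test_every_fixture_decision_matches_generator_truth(fixture_run):
    truth = fixture_run.truth.record_category
    for d in fixture_run.screen_decisions:
        if d.included:
            assert truth[d.record_id] == "included"
        else:
            assert truth[d.record_id] == d.reason_code
    cohort_truth = fixture_run.truth.cohort_status
    for d in fixture_run.cohort.decisions:
        expected = "cohort" if d.included else d.reason_code
        assert cohort_truth[d.record_id] == expected
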