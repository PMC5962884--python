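#!/usr/bin/env python
"""Generate the synthetic audit corpus realizing the published flow plan.

Writes the fixture inputs (corpus, disclosure list, survey table, truth
sidecar) under results/fixture/ and reports the headline sizes.
"""

from pathlib import Path

from fundingaudit import synth
from fundingaudit.records import (write_disclosure_list, write_records,
                                  write_survey_outcomes)

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"


def main() -> None:
    spec = synth.load_flow_spec()
    records, disclosure, survey, truth = synth.generate_flow_fixture(spec)
    write_records(records, OUT / "corpus.jsonl")
    write_disclosure_list(disclosure, OUT / "disclosure.csv")
    write_survey_outcomes(survey, OUT / "survey.csv")
    synth.write_truth(truth, OUT / "truth.jsonl")
    print(f"corpus: {len(records)} records "
          f"(plan: Sample 1 = {spec.n_sample1}, Sample 2 = {spec.n_sample2}, "
          f"cohort = {spec.n_cohort} studies / "
          f"{spec.roster_plan['cohort_authors']} authors)")
    print(f"disclosure list: {len(disclosure)} names "
          f"({spec.roster_plan['planted_matches']} planted correspondences)")
    print(f"survey: {len(survey)} corresponding-author outcomes")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
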