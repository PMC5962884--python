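#!/usr/bin/env python
"""Match cohort authors to the disclosure list; coverage and survey results.

Writes matches.csv, coverage.json and survey.json under results/audit/ and
prints the coverage accounting.
"""

import json

from _config import AUDIT, audit_config
from fundingaudit.pipeline import run_pipeline


def main() -> None:
    run_pipeline(audit_config(("screen", "match")))
    cov = json.loads((AUDIT / "coverage.json").read_text())
    print(f"matched {cov['n_matched']} of {cov['n_cohort_authors']} cohort "
          f"authors to the {cov['n_disclosure_names']}-name disclosure list")
    print(f"  = {cov['pct_of_cohort']}% of the funded-author roster, "
          f"{cov['pct_of_disclosure']}% of the disclosure list")
    print(f"disclosure names with no funded publication found: "
          f"{cov['n_unmatched_disclosure']}")
    print(f"after removing every publication with a matched author: "
          f"{cov['unmatched_authors']} authors on "
          f"{cov['unmatched_articles']} articles remain unacknowledged")
    surv = json.loads((AUDIT / "survey.json").read_text())
    for cat, row in surv["tally"].items():
        if cat != "total":
            print(f"survey {cat:>15}: {row['count']:>3} ({row['pct']}%)")
    print(f"after survey adjustments: {surv['adjusted_authors']} authors on "
          f"{surv['adjusted_articles']} articles")


if __name__ == "__main__":
    main()
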