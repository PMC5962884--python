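#!/usr/bin/env python
"""Screening cascade: prefilter, direct-funding screen, samples, cohort.

Writes the PRISMA ledger under results/audit/ and prints the stage flow.
"""

import json

from _config import AUDIT, audit_config
from fundingaudit.pipeline import run_pipeline


def main() -> None:
    run_pipeline(audit_config(("screen",)))
    ledger = json.loads((AUDIT / "prisma_ledger.json").read_text())
    for st in ledger["stages"]:
        reasons = ", ".join(f"{k}={v}"
                            for k, v in sorted(st["reasons"].items()))
        print(f"{st['stage']:>24}: {st['input']:>4} -> {st['output']:>4}"
              f"  excluded {st['excluded']:>3}"
              + (f"  ({reasons})" if reasons else ""))
    summary = json.loads((AUDIT / "screen_summary.json").read_text())
    print(f"\ntransparency cohort: {summary['n_cohort_records']} studies, "
          f"{summary['n_cohort_authors']} unique authors after "
          f"name disambiguation")


if __name__ == "__main__":
    main()
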