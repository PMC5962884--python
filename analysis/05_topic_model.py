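#!/usr/bin/env python
"""Latent topics in the funded abstracts (Sample 2).

Fits the collapsed-Gibbs topic model and prints each topic's document
share, mean dominance ratio and top stems; tables land in results/audit/.
"""

import json

from _config import AUDIT, audit_config
from fundingaudit.pipeline import run_pipeline


def main() -> None:
    run_pipeline(audit_config(("screen", "match", "network", "topics")))
    top = json.loads((AUDIT / "topics.json").read_text())
    shares = top["shares_pct"]
    print(f"fitted k={top['k']} topics over {top['n_documents']} abstracts")
    for t in sorted(shares, key=lambda x: -shares[x]):
        words = " ".join(top["top_words"][t][:7])
        ratio = top["mean_ratio"][t]
        print(f"topic {t}: {shares[t]:>5}% of documents, "
              f"mean dominance ratio {ratio}; top stems: {words}")


if __name__ == "__main__":
    main()
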