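#!/usr/bin/env python
"""Fold all pipeline artifacts into the combined markdown report."""

from _config import AUDIT
from fundingaudit.pipeline import render_reports


def main() -> None:
    print(render_reports(AUDIT))
    print(f"(written to {AUDIT / 'report.md'})")


if __name__ == "__main__":
    main()
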