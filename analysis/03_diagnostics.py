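#!/usr/bin/env python
"""Step 3 — diagnostic test characteristics of the dichotomized prediction.

Cross-classifies predictions against observed 28-day outcomes and computes
sensitivity, specificity, predictive values (continuity-corrected score
CIs), likelihood ratios, the terminal-probability AUC, and the cohort's
mean predicted mortality.  Writes both JSON and an aligned-text table.
"""

import json
from pathlib import Path

from persevere.diagnostics import contingency, diagnostic_report, report_to_text
from persevere.io import read_cohort
from persevere.tree import classify_cohort, load_default_tree

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort(OUT / "cohort.csv")
    tree = load_default_tree()
    assignments = classify_cohort(records, tree)
    outcomes = [r.died_28d for r in records]
    table = contingency(assignments, outcomes)
    report = diagnostic_report(table, assignments, outcomes)
    (OUT / "diagnostics.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    text = report_to_text(report)
    (OUT / "diagnostics.txt").write_text(text + "\n", encoding="utf-8")
    print(text)
    print(f"-> {OUT / 'diagnostics.json'}")


if __name__ == "__main__":
    main()
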