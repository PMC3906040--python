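#!/usr/bin/env python
"""Step 5 — clinical course of false positives vs true negatives.

Among survivors only, contrasts those predicted to die (false positives)
against those predicted to survive (true negatives) on PICU length of
stay, PICU free days, and organ-failure burden/persistence; also writes
the overall cohort summary.
"""

import json
from pathlib import Path

from persevere.cohort import cohort_summary, fp_tn_comparison
from persevere.io import read_cohort
from persevere.tree import classify_cohort, load_default_tree

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort(OUT / "cohort.csv")
    tree = load_default_tree()
    assignments = classify_cohort(records, tree)
    rows = fp_tn_comparison(records, assignments)
    summary = cohort_summary(records)
    payload = {
        "fp_tn_comparison": [c.to_dict() for c in rows],
        "cohort_summary": summary,
    }
    (OUT / "fp_tn_comparison.json").write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    width = max(len(c.variable) for c in rows) + 2
    print(f"{'variable':<{width}}{'true negatives':<18}{'false positives':<18}p")
    for c in rows:
        p = "n/a" if c.p_value is None else f"{c.p_value:.3g}"
        print(f"{c.variable:<{width}}{c.summary_a:<18}{c.summary_b:<18}{p} ({c.test})")
    print(f"overall mortality: {summary['mortality_percent']}%")
    print(f"-> {OUT / 'fp_tn_comparison.json'}")


if __name__ == "__main__":
    main()
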