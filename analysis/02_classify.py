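#!/usr/bin/env python
"""Step 2 — risk-stratify the cohort with the decision tree.

Applies the packaged tree to every subject, writes the assignment table
(terminal node, mortality probability, risk class, dichotomized prediction
at the 2.5% cut-off) and reports the risk-class partition.
"""

from pathlib import Path

from persevere.io import read_cohort, write_assignments
from persevere.tree import classify_cohort, load_default_tree, risk_class_counts

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort(OUT / "cohort.csv")
    tree = load_default_tree()
    assignments = classify_cohort(records, tree)
    write_assignments(assignments, OUT / "assignments.csv")
    counts = risk_class_counts(assignments)
    predicted_dead = sum(a.predicted_nonsurvivor for a in assignments)
    print(f"classified {len(assignments)} subjects with tree '{tree.name}'")
    print(f"  risk classes: {counts}")
    print(f"  predicted survivors {len(assignments) - predicted_dead}, "
          f"predicted non-survivors {predicted_dead}")
    print(f"  -> {OUT / 'assignments.csv'}")


if __name__ == "__main__":
    main()
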