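#!/usr/bin/env python
"""Step 4 — net reclassification improvement over the PRISM baseline.

Fits a univariable logistic model of 28-day mortality on the PRISM
physiology score (complete-case), pairs each subject's baseline risk with
the tree's terminal-node probability, and computes the category-free NRI
with its asymptotic CI and p-value.
"""

import json
from pathlib import Path

from persevere.io import read_cohort
from persevere.pipeline import run_pipeline
from persevere.tree import load_default_tree

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort(OUT / "cohort.csv")
    tree = load_default_tree()
    bundle = run_pipeline(records, tree, command="nri", inputs=("results/cohort.csv",))
    if bundle.nri is None:
        print(f"NRI not computable: {bundle.nri_notice}")
        return
    res = bundle.nri
    (OUT / "nri.json").write_text(
        json.dumps({"nri": res.to_dict(), "notice": bundle.nri_notice}, indent=2) + "\n",
        encoding="utf-8",
    )
    print(bundle.nri_notice)
    print(f"NRI = {res.nri:.3f} (95% CI {res.ci_low:.3f} to {res.ci_high:.3f}; "
          f"p = {res.p_value:.3g})")
    print(f"  event component {res.event_component:+.3f} over {res.n_events} deaths; "
          f"nonevent component {res.nonevent_component:+.3f} over {res.n_nonevents} survivors")
    print(f"-> {OUT / 'nri.json'}")


if __name__ == "__main__":
    main()
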