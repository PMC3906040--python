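"""End-to-end evaluation pipeline: classify -> test statistics -> NRI -> FP/TN.

Runs the full prognostic-accuracy evaluation on a cohort, in the order the
stages depend on each other: risk classification of every subject,
diagnostic test characteristics of the dichotomized prediction, net
reclassification improvement over a PRISM-only baseline (when PRISM is
available), the false-positive vs true-negative clinical-course contrast,
and the cohort summary.  Every bundle embeds a manifest recording the tree
version, cut-off, confidence level and seed used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import cohort as cohort_mod
from . import diagnostics as diag_mod
from . import reclassification as reclass_mod
from .io import RunManifest
from .tree import (
    DEFAULT_CUTOFF,
    RiskAssignment,
    TreeSpec,
    classify_cohort,
    risk_class_counts,
)

__all__ = ["ReportBundle", "run_pipeline"]

#: Minimum subjects per outcome class with PRISM for the baseline logistic fit.
_MIN_PER_CLASS = 2


@dataclass(frozen=True)
class ReportBundle:
    """Everything one evaluation run produces."""

    manifest: RunManifest
    assignments: list[RiskAssignment]
    risk_class_counts: dict
    diagnostics: diag_mod.DiagnosticReport
    nri: Optional[reclass_mod.NRIResult]
    nri_notice: str
    fp_tn: list[cohort_mod.GroupComparison]
    cohort_summary: dict

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest.to_dict(),
            "risk_class_counts": self.risk_class_counts,
            "diagnostics": self.diagnostics.to_dict(),
            "nri": None if self.nri is None else self.nri.to_dict(),
            "nri_notice": self.nri_notice,
            "fp_tn_comparison": [c.to_dict() for c in self.fp_tn],
            "cohort_summary": self.cohort_summary,
        }


def run_pipeline(
    records: Sequence[cohort_mod.CohortRecord],
    tree: TreeSpec,
    cutoff: float = DEFAULT_CUTOFF,
    conf: float = 0.95,
    command: str = "report",
    inputs: Sequence[str] = (),
    seed: Optional[int] = None,
) -> ReportBundle:
    """Run every evaluation stage on ``records`` and bundle the results."""
    assignments = classify_cohort(records, tree, cutoff=cutoff)
    outcomes = [r.died_28d for r in records]
    table = diag_mod.contingency(assignments, outcomes)
    report = diag_mod.diagnostic_report(table, assignments, outcomes, conf=conf)

    with_prism = [
        (r, a) for r, a in zip(records, assignments) if r.prism is not None
    ]
    n_events = sum(r.died_28d for r, _ in with_prism)
    n_nonevents = len(with_prism) - n_events
    if not any(r.prism is not None for r in records):
        nri, notice = None, "PRISM not available; NRI stage skipped"
    elif n_events < _MIN_PER_CLASS or n_nonevents < _MIN_PER_CLASS:
        nri, notice = None, (
            "too few complete-case subjects per outcome class for the "
            "PRISM baseline fit; NRI stage skipped"
        )
    else:
        p_base = reclass_mod.baseline_probabilities(
            [r.prism for r, _ in with_prism], [r.died_28d for r, _ in with_prism]
        )
        pairs = [
            reclass_mod.RiskPair(
                p_baseline=float(pb),
                p_new=a.mortality_probability,
                event=r.died_28d,
            )
            for (r, a), pb in zip(with_prism, p_base)
        ]
        nri = reclass_mod.nri_continuous(pairs, conf=conf)
        dropped = len(records) - len(with_prism)
        notice = (
            f"complete-case NRI on {len(with_prism)} subjects"
            + (f" ({dropped} without PRISM excluded)" if dropped else "")
        )

    fp_tn = cohort_mod.fp_tn_comparison(records, assignments)
    summary = cohort_mod.cohort_summary(records)

    manifest = RunManifest(
        command=command,
        inputs=tuple(str(p) for p in inputs),
        tree_name=tree.name,
        cutoff=cutoff,
        conf=conf,
        seed=seed,
    )
    return ReportBundle(
        manifest=manifest,
        assignments=list(assignments),
        risk_class_counts=risk_class_counts(assignments),
        diagnostics=report,
        nri=nri,
        nri_notice=notice,
        fp_tn=fp_tn,
        cohort_summary=summary,
    )
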