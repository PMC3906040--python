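"""Clinical-course variables and secondary group comparisons.

Covers the descriptive side of the evaluation: PICU free days, cohort
summary tables (medians with interquartile ranges, counts with percents,
mortality), and the contrast of false positives (survivors predicted to
die) against true negatives (survivors predicted to survive) on PICU length
of stay, PICU free days, organ-failure burden and organ-failure persistence.

Continuous contrasts use the Mann-Whitney U-test (exact enumeration for
small tie-free samples, normal approximation with tie correction
otherwise); 2x2 tables use Fisher's exact test when any expected cell count
is below 5 and the continuity-corrected chi-square test otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .tree import BiomarkerProfile, RiskAssignment

__all__ = [
    "CohortRecord",
    "GroupComparison",
    "picu_free_days",
    "mann_whitney",
    "categorical_test",
    "fp_tn_comparison",
    "cohort_summary",
]


@dataclass(frozen=True)
class CohortRecord:
    """One subject: biomarker profile, outcome, and clinical-course data."""

    subject_id: str
    profile: BiomarkerProfile
    died_28d: bool
    prism: Optional[float] = None
    picu_los_days: Optional[float] = None
    max_organ_failures: Optional[int] = None
    organ_failures_ge2_day7: Optional[bool] = None
    comorbidity: Optional[bool] = None
    immune_suppression: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.picu_los_days is not None and self.picu_los_days < 0:
            raise ValueError(f"{self.subject_id}: negative PICU length of stay")
        if self.max_organ_failures is not None and self.max_organ_failures < 0:
            raise ValueError(f"{self.subject_id}: negative organ-failure count")


@dataclass(frozen=True)
class GroupComparison:
    """One row of a two-group contrast table."""

    variable: str
    summary_a: str
    summary_b: str
    test: str
    p_value: Optional[float]

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "group_a": self.summary_a,
            "group_b": self.summary_b,
            "test": self.test,
            "p_value": self.p_value,
        }


def picu_free_days(los_days: float, died_28d: bool) -> int:
    """Days alive and out of the PICU within a 28-day window.

    28 minus the (whole-day) length of stay; zero for subjects who died
    within 28 days or stayed longer than 28 days.
    """
    if los_days < 0 or not math.isfinite(los_days):
        raise ValueError(f"invalid PICU length of stay {los_days!r}")
    if died_28d or los_days > 28:
        return 0
    return 28 - int(math.floor(los_days))


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test; returns (U statistic, p-value).

    Exact enumeration when both groups have at most 8 observations and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def categorical_test(table: Sequence[Sequence[int]]) -> tuple[str, float]:
    """2x2 association test; returns (test name, two-sided p-value).

    Fisher's exact test when any expected cell count is below 5, otherwise
    the chi-square test with continuity correction.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        # Degenerate margin: no association is testable.
        return "fisher", 1.0
    expected = row @ col / t.sum()
    if expected.min() < 5:
        _, p = stats.fisher_exact(t.astype(int))
        return "fisher", float(p)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return "chi-square", float(p)


def _median_iqr(values: Sequence[float]) -> str:
    v = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return f"{q50:g} ({q25:g}-{q75:g})"


def _count_pct(k: int, n: int) -> str:
    pct = 0.0 if n == 0 else 100.0 * k / n
    return f"{k} ({pct:.0f}%)"


def fp_tn_comparison(
    cohort: Sequence[CohortRecord],
    assignments: Sequence[RiskAssignment],
) -> list[GroupComparison]:
    """Clinical course of true negatives (group A) vs false positives (B).

    Both groups contain survivors only: true negatives are predicted
    survivors, false positives are predicted non-survivors.  Compares PICU
    length of stay, PICU free days, maximum organ failures over the first 7
    days (Mann-Whitney), and persistence of >= 2 organ failures at day 7
    (categorical test).  An empty group flags every row as not computable.
    """
    by_id = {a.subject_id: a for a in assignments}
    missing = [r.subject_id for r in cohort if r.subject_id not in by_id]
    if missing:
        raise ValueError(f"no assignment for subjects: {', '.join(missing)}")
    tn = [r for r in cohort if not r.died_28d and not by_id[r.subject_id].predicted_nonsurvivor]
    fp = [r for r in cohort if not r.died_28d and by_id[r.subject_id].predicted_nonsurvivor]

    rows: list[GroupComparison] = []
    if not tn or not fp:
        note = f"not computable (TN n={len(tn)}, FP n={len(fp)})"
        for var in (
            "PICU length of stay, days",
            "PICU free days",
            "Maximum number of organ failures",
            ">=2 organ failures at PICU day 7",
        ):
            rows.append(GroupComparison(var, "-", "-", note, None))
        return rows

    def continuous(var: str, getter) -> GroupComparison:
        va = [getter(r) for r in tn if getter(r) is not None]
        vb = [getter(r) for r in fp if getter(r) is not None]
        _, p = mann_whitney(va, vb)
        return GroupComparison(var, _median_iqr(va), _median_iqr(vb), "mann-whitney", p)

    rows.append(continuous("PICU length of stay, days", lambda r: r.picu_los_days))
    rows.append(
        continuous(
            "PICU free days",
            lambda r: None
            if r.picu_los_days is None
            else picu_free_days(r.picu_los_days, r.died_28d),
        )
    )
    rows.append(continuous("Maximum number of organ failures", lambda r: r.max_organ_failures))

    ka = sum(bool(r.organ_failures_ge2_day7) for r in tn)
    kb = sum(bool(r.organ_failures_ge2_day7) for r in fp)
    test, p = categorical_test([[ka, len(tn) - ka], [kb, len(fp) - kb]])
    rows.append(
        GroupComparison(
            ">=2 organ failures at PICU day 7",
            _count_pct(ka, len(tn)),
            _count_pct(kb, len(fp)),
            test,
            p,
        )
    )
    return rows


def cohort_summary(cohort: Sequence[CohortRecord]) -> dict:
    """Demographics/clinical summary split by 28-day outcome.

    Medians with IQR for age and PRISM (complete-case), counts with percent
    for the categorical flags, and overall mortality percent.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")

    def block(records: Sequence[CohortRecord]) -> dict:
        n = len(records)
        out: dict = {"n": n}
        if n:
            out["age_median_iqr"] = _median_iqr([r.profile.age for r in records])
            prism = [r.prism for r in records if r.prism is not None]
            out["prism_median_iqr"] = _median_iqr(prism) if prism else "n/a"
            out["prism_missing"] = n - len(prism)
            out["comorbidity"] = _count_pct(
                sum(bool(r.comorbidity) for r in records), n
            )
            out["immune_suppression"] = _count_pct(
                sum(bool(r.immune_suppression) for r in records), n
            )
        return out

    died = [r for r in cohort if r.died_28d]
    survived = [r for r in cohort if not r.died_28d]
    return {
        "all": block(list(cohort)),
        "survivors": block(survived),
        "nonsurvivors": block(died),
        "mortality_percent": round(100.0 * len(died) / len(cohort), 1),
    }
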