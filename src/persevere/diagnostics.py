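"""Diagnostic test characteristics with score-method confidence intervals.

Given dichotomized predictions (predicted non-survivor vs predicted survivor)
and observed 28-day outcomes, this module computes the standard prognostic
test statistics: sensitivity, specificity, predictive values, likelihood
ratios, a tie-aware rank AUC, and the cohort's mean predicted mortality.

Binomial proportions carry 95% confidence intervals from the *continuity-
corrected* Wilson score method (the "score method" of the classic online
clinical calculators).  Likelihood-ratio intervals use the standard log
method; the AUC interval uses DeLong's variance estimator by default, with
the Hanley-McNeil approximation available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .tree import RiskAssignment

__all__ = [
    "ContingencyTable",
    "ProportionEstimate",
    "RatioEstimate",
    "ValueWithCI",
    "DiagnosticReport",
    "contingency",
    "proportion_with_score_ci",
    "likelihood_ratio_ci",
    "auc_rank",
    "overall_predicted_mortality",
    "diagnostic_report",
    "report_to_text",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification of prediction vs 28-day outcome.

    tp: predicted non-survivor who died; fp: predicted non-survivor who
    survived; tn: predicted survivor who survived; fn: predicted survivor
    who died.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_died(self) -> int:
        return self.tp + self.fn

    @property
    def n_survived(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its score-method confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    conf: float = 0.95


@dataclass(frozen=True)
class RatioEstimate:
    """A likelihood ratio with a log-method confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    conf: float = 0.95


@dataclass(frozen=True)
class ValueWithCI:
    point: float
    ci_low: float
    ci_high: float
    conf: float = 0.95


@dataclass(frozen=True)
class DiagnosticReport:
    """All Table-style test characteristics of a dichotomized classifier.

    Any statistic whose denominator is zero is ``None`` and its name is
    recorded in ``undefined`` rather than silently dropped.
    """

    table: ContingencyTable
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]
    lr_pos: Optional[RatioEstimate]
    lr_neg: Optional[RatioEstimate]
    auc: Optional[ValueWithCI]
    overall_predicted_mortality: Optional[ValueWithCI]
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def conv(x):
            if x is None:
                return None
            return asdict(x)

        return {
            "n": self.table.total,
            "contingency": asdict(self.table),
            "sensitivity": conv(self.sensitivity),
            "specificity": conv(self.specificity),
            "ppv": conv(self.ppv),
            "npv": conv(self.npv),
            "lr_pos": conv(self.lr_pos),
            "lr_neg": conv(self.lr_neg),
            "auc": conv(self.auc),
            "overall_predicted_mortality": conv(self.overall_predicted_mortality),
            "undefined": list(self.undefined),
        }


def _as_died_bool(outcomes: Sequence) -> np.ndarray:
    out = []
    for o in outcomes:
        if isinstance(o, str):
            if o not in ("died", "survived"):
                raise ValueError(f"unknown outcome label {o!r}")
            out.append(o == "died")
        else:
            out.append(bool(o))
    return np.asarray(out, dtype=bool)


def contingency(
    assignments: Sequence[RiskAssignment],
    outcomes,
) -> ContingencyTable:
    """Cross-classify predictions against observed 28-day outcomes.

    ``outcomes`` is either a sequence aligned with ``assignments`` (booleans,
    True = died, or the labels "died"/"survived") or a mapping from
    subject_id to such a value; with a mapping, every assignment's subject id
    must be present.
    """
    if isinstance(outcomes, Mapping):
        missing = [a.subject_id for a in assignments if a.subject_id not in outcomes]
        if missing:
            raise ValueError(f"outcomes missing for subjects: {', '.join(missing)}")
        outcome_seq = [outcomes[a.subject_id] for a in assignments]
    else:
        if len(outcomes) != len(assignments):
            raise ValueError(
                f"length mismatch: {len(assignments)} assignments vs "
                f"{len(outcomes)} outcomes"
            )
        outcome_seq = list(outcomes)
    died = _as_died_bool(outcome_seq)
    pred = np.asarray([a.predicted_nonsurvivor for a in assignments], dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(pred & died)),
        fp=int(np.sum(pred & ~died)),
        tn=int(np.sum(~pred & ~died)),
        fn=int(np.sum(~pred & died)),
    )


def proportion_with_score_ci(k: int, n: int, conf: float = 0.95) -> ProportionEstimate:
    """Binomial proportion with the continuity-corrected Wilson score interval.

    The continuity-corrected form (Newcombe's method 4) is used, matching the
    score-method intervals of the classic clinical-statistics calculators:

        L = [2np + z^2 - 1 - z*sqrt(z^2 - 2 - 1/n + 4p(nq + 1))] / [2(n + z^2)]
        U = [2np + z^2 + 1 + z*sqrt(z^2 + 2 - 1/n + 4p(nq - 1))] / [2(n + z^2)]

    with p = k/n, q = 1 - p, truncated to [0, 1]; L = 0 when k = 0 and
    U = 1 when k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k = {k} outside [0, {n}]")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    p = k / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    if k == 0:
        lo = 0.0
    else:
        lo = (2 * n * p + z * z - 1 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1))) / denom
    if k == n:
        hi = 1.0
    else:
        hi = (2 * n * p + z * z + 1 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1))) / denom
    return ProportionEstimate(
        point=p,
        ci_low=max(0.0, lo),
        ci_high=min(1.0, hi),
        numerator=int(k),
        denominator=int(n),
        conf=conf,
    )


def likelihood_ratio_ci(
    table: ContingencyTable, positive: bool, conf: float = 0.95
) -> Optional[RatioEstimate]:
    """Likelihood ratio with a log-method confidence interval.

    LR+ = sens / (1 - spec), LR- = (1 - sens) / spec.  The log-scale standard
    error is sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) with (a, c) the numerator
    cells.  Returns None when a required denominator is zero.
    """
    tp, fp, tn, fn = table.tp, table.fp, table.tn, table.fn
    n_d, n_s = table.n_died, table.n_survived
    if n_d == 0 or n_s == 0:
        return None
    sens = tp / n_d
    spec = tn / n_s
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    if positive:
        if spec == 1.0:
            return None
        point = sens / (1.0 - spec)
        if tp == 0 or fp == 0:
            return RatioEstimate(point, math.nan, math.nan, conf)
        se = math.sqrt(1 / tp - 1 / n_d + 1 / fp - 1 / n_s)
    else:
        if spec == 0.0:
            return None
        point = (1.0 - sens) / spec
        if fn == 0 or tn == 0:
            return RatioEstimate(point, math.nan, math.nan, conf)
        se = math.sqrt(1 / fn - 1 / n_d + 1 / tn - 1 / n_s)
    if point == 0.0:
        return RatioEstimate(point, math.nan, math.nan, conf)
    return RatioEstimate(
        point=point,
        ci_low=point * math.exp(-z * se),
        ci_high=point * math.exp(z * se),
        conf=conf,
    )


def auc_rank(
    probabilities: Sequence[float],
    outcomes,
    conf: float = 0.95,
    ci_method: str = "delong",
) -> ValueWithCI:
    """Tie-aware rank (Mann-Whitney) AUC with a confidence interval.

    Concordant (death ranked above survivor) pairs count 1, tied-probability
    pairs count 1/2, divided by n_died * n_survived.  ``ci_method`` is
    "delong" (default) or "hanley-mcneil"; intervals are truncated to [0, 1].
    """
    x = np.asarray(probabilities, dtype=float)
    died = _as_died_bool(outcomes)
    if len(x) != len(died):
        raise ValueError("probabilities and outcomes differ in length")
    pos = x[died]
    neg = x[~died]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present to compute an AUC")
    # Placement values: for each death, the fraction of survivors it outranks
    # (ties count 1/2); and symmetrically for survivors.  Their means equal
    # the AUC and their variances feed DeLong's estimator.
    v10 = np.empty(m)
    for i, xi in enumerate(pos):
        v10[i] = (np.sum(xi > neg) + 0.5 * np.sum(xi == neg)) / n
    v01 = np.empty(n)
    for j, xj in enumerate(neg):
        v01[j] = (np.sum(pos > xj) + 0.5 * np.sum(pos == xj)) / m
    auc = float(v10.mean())
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    if ci_method == "delong":
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
            np.var(v01, ddof=1) / n if n > 1 else 0.0
        )
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc * auc / (1.0 + auc)
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    half = z * math.sqrt(max(var, 0.0))
    return ValueWithCI(
        point=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        conf=conf,
    )


def overall_predicted_mortality(
    assignments: Sequence[RiskAssignment], conf: float = 0.95
) -> ValueWithCI:
    """Mean of the assigned terminal-node mortality probabilities, with a
    normal-approximation CI (mean +/- z * SD / sqrt(n), truncated to [0, 1])."""
    if len(assignments) == 0:
        raise ValueError("no assignments")
    p = np.asarray([a.mortality_probability for a in assignments], dtype=float)
    mean = float(p.mean())
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    se = float(p.std(ddof=1) / math.sqrt(len(p))) if len(p) > 1 else 0.0
    return ValueWithCI(
        point=mean,
        ci_low=max(0.0, mean - z * se),
        ci_high=min(1.0, mean + z * se),
        conf=conf,
    )


def diagnostic_report(
    table: ContingencyTable,
    assignments: Optional[Sequence[RiskAssignment]] = None,
    outcomes=None,
    conf: float = 0.95,
) -> DiagnosticReport:
    """Assemble the full battery of test characteristics from a 2x2 table.

    When ``assignments`` (and, for the AUC, ``outcomes``) are supplied, the
    mean predicted mortality and the terminal-probability AUC are included.
    """
    undefined: list[str] = []

    def prop(k: int, n: int, name: str) -> Optional[ProportionEstimate]:
        if n == 0:
            undefined.append(name)
            return None
        return proportion_with_score_ci(k, n, conf)

    sens = prop(table.tp, table.n_died, "sensitivity")
    spec = prop(table.tn, table.n_survived, "specificity")
    ppv = prop(table.tp, table.tp + table.fp, "ppv")
    npv = prop(table.tn, table.tn + table.fn, "npv")
    lr_pos = likelihood_ratio_ci(table, positive=True, conf=conf)
    if lr_pos is None:
        undefined.append("lr_pos")
    lr_neg = likelihood_ratio_ci(table, positive=False, conf=conf)
    if lr_neg is None:
        undefined.append("lr_neg")
    auc = None
    opm = None
    if assignments is not None:
        opm = overall_predicted_mortality(assignments, conf)
        if outcomes is not None:
            try:
                auc = auc_rank(
                    [a.mortality_probability for a in assignments], outcomes, conf
                )
            except ValueError:
                undefined.append("auc")
    return DiagnosticReport(
        table=table,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=auc,
        overall_predicted_mortality=opm,
        undefined=tuple(undefined),
    )


def _pct(est: Optional[ProportionEstimate]) -> str:
    if est is None:
        return "undefined"
    return (
        f"{round(est.point * 100):d}% "
        f"({round(est.ci_low * 100):d}-{round(est.ci_high * 100):d})"
    )


def report_to_text(report: DiagnosticReport) -> str:
    """Aligned-text rendering with the conventional row names and rounding
    (proportions to whole percent, likelihood ratios to 1 decimal, AUC to 3)."""
    t = report.table
    rows = [
        ("Number of Subjects", str(t.total)),
    ]
    if report.overall_predicted_mortality is not None:
        o = report.overall_predicted_mortality
        rows.append(
            (
                "Overall Predicted Mortality",
                f"{o.point * 100:.1f}% ({o.ci_low * 100:.1f}-{o.ci_high * 100:.1f})",
            )
        )
    rows += [
        ("Number of True Positives", str(t.tp)),
        ("Number of True Negatives", str(t.tn)),
        ("Number of False Positives", str(t.fp)),
        ("Number of False Negatives", str(t.fn)),
        ("Sensitivity", _pct(report.sensitivity)),
        ("Specificity", _pct(report.specificity)),
        ("Positive Predictive Value", _pct(report.ppv)),
        ("Negative Predictive Value", _pct(report.npv)),
    ]
    for label, lr in (("+Likelihood Ratio", report.lr_pos), ("-Likelihood Ratio", report.lr_neg)):
        if lr is None:
            rows.append((label, "undefined"))
        else:
            ci = "" if math.isnan(lr.ci_low) else f" ({lr.ci_low:.1f}-{lr.ci_high:.1f})"
            rows.append((label, f"{lr.point:.1f}{ci}"))
    if report.auc is not None:
        a = report.auc
        rows.append(("Area Under the Curve", f"{a.point:.3f} ({a.ci_low:.3f}-{a.ci_high:.3f})"))
    width = max(len(r[0]) for r in rows) + 2
    return "\n".join(f"{name:<{width}}{value}" for name, value in rows)
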