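"""Seeded synthetic-cohort generator for end-to-end pipeline testing.

No patient-level data accompany the published model, so every pipeline
stage is exercised on simulated cohorts with the same statistical structure
the analysis assumes:

* terminal-node membership is multinomial over a configured occupancy
  (or exact counts, for reproducing printed cohort partitions);
* biomarker/age vectors are drawn uniformly inside the terminal node's
  admissible region, so each subject classifies back to its generating
  node by construction;
* 28-day death is Bernoulli per node, or exactly ``round(n_node * p_node)``
  deaths per node in the deterministic-allocation mode;
* PRISM severity scores come from outcome-conditional gamma distributions
  calibrated to the published survivor/non-survivor medians and IQRs
  (11 [8-15] vs 19 [13-25]);
* PICU length of stay and organ-failure variables are drawn conditionally
  on (predicted risk class, outcome) so that, when configured, false
  positives run sicker courses than true negatives.

Reproducibility: one seed drives a named substream per variable family, so
the same config + seed always yields a byte-identical cohort table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import CohortRecord
from .tree import BIOMARKERS, BiomarkerProfile, TreeSpec, TreeSpecError, load_default_tree

__all__ = [
    "Interval",
    "PathConstraint",
    "GeneratorConfig",
    "path_constraints",
    "generate_cohort",
    "cohort_2014_config",
]

#: Age range (years) used when a path leaves age unconstrained.
AGE_RANGE = (0.0, 18.0)

# Gamma (shape, scale) pairs fitted by quartile matching to the published
# severity summaries: PRISM 11 (8-15) survivors vs 19 (13-25) non-survivors;
# PICU stay 4 (3-9) days for true negatives, 7 (4-13) for false positives,
# and a 4 (2-6)-day stay for non-survivors (median days to death 4).
PRISM_GAMMA = {"survivor": (4.8377, 2.4587), "nonsurvivor": (4.7290, 4.2228)}
LOS_GAMMA = {"tn": (1.3064, 4.8516), "fp": (1.4550, 6.4553), "died": (1.9857, 2.2726)}

# Discrete distributions for the maximum organ-failure count over PICU days
# 1-7, chosen to match the published medians/IQRs: 1 (1-2) for true
# negatives, 3 (2-3) for false positives; deaths skew higher.
ORGAN_FAILURE_PMF = {
    "tn": {0: 0.05, 1: 0.55, 2: 0.30, 3: 0.08, 4: 0.02},
    "fp": {1: 0.10, 2: 0.25, 3: 0.45, 4: 0.15, 5: 0.05},
    "died": {2: 0.10, 3: 0.30, 4: 0.40, 5: 0.20},
}

# P(>=2 organ failures persisting at day 7): 10% true negatives vs 46%
# false positives as published; deaths assumed mostly persistent.
OF_DAY7_PROB = {"tn": 0.10, "fp": 0.46, "died": 0.80}


@dataclass(frozen=True)
class Interval:
    """Admissible values of one decision variable along a tree path.

    ``lower_open`` marks a strict lower bound (value > lower); the upper
    bound is inclusive for a ``<=`` split and strict for ``<``.
    """

    lower: float
    upper: float
    lower_open: bool = True
    upper_closed: bool = True

    def is_empty(self) -> bool:
        if self.lower > self.upper:
            return True
        if self.lower == self.upper:
            return not (not self.lower_open and self.upper_closed)
        return False


@dataclass(frozen=True)
class PathConstraint:
    """Per-variable admissible intervals for one terminal node."""

    terminal_id: str
    intervals: Mapping[str, Interval]


def _global_ranges(tree: TreeSpec) -> dict[str, tuple[float, float]]:
    """Default sampling range per variable: 0 to 10x the largest threshold
    seen for that variable anywhere in the tree (biomarkers), 0-18 years
    for age; variables never split on share the overall biomarker cap."""
    ranges: dict[str, tuple[float, float]] = {}
    thresholds: dict[str, float] = {}
    for rule in tree.splits.values():
        thresholds[rule.variable] = max(thresholds.get(rule.variable, 0.0), rule.threshold)
    fallback_cap = 10.0 * max(thresholds.values(), default=100.0)
    for var in BIOMARKERS:
        cap = 10.0 * thresholds[var] if var in thresholds else fallback_cap
        ranges[var] = (0.0, cap)
    ranges["age"] = AGE_RANGE if "age" not in thresholds else (
        0.0, max(AGE_RANGE[1], 10.0 * thresholds["age"])
    )
    return ranges


def path_constraints(tree: TreeSpec, terminal_id: str) -> PathConstraint:
    """Intersect all ancestor split half-lines into per-variable intervals.

    Variables not split on along the path get the global sampling range.
    Raises if the intersection is empty (a contradictory path).
    """
    ranges = _global_ranges(tree)
    intervals = {
        var: Interval(lo, hi, lower_open=False, upper_closed=True)
        for var, (lo, hi) in ranges.items()
    }
    for rule in tree.path_to(terminal_id):
        cur = intervals[rule.variable]
        went_low = _descends_to(tree, rule.low_child, terminal_id)
        if went_low:
            # value <= t (op "<=") or value < t (op "<")
            if rule.threshold < cur.upper or (
                rule.threshold == cur.upper and rule.op == "<" and cur.upper_closed
            ):
                cur = replace(cur, upper=rule.threshold, upper_closed=(rule.op == "<="))
        else:
            # value > t (op "<=") or value >= t (op "<")
            if rule.threshold > cur.lower or (
                rule.threshold == cur.lower and rule.op == "<=" and not cur.lower_open
            ):
                cur = replace(cur, lower=rule.threshold, lower_open=(rule.op == "<="))
        if cur.is_empty():
            raise TreeSpecError(
                f"contradictory constraints for {rule.variable!r} on the path "
                f"to {terminal_id!r} (at split {rule.node_id})"
            )
        intervals[rule.variable] = cur
    return PathConstraint(terminal_id=terminal_id, intervals=dict(intervals))


def _descends_to(tree: TreeSpec, node: str, terminal_id: str) -> bool:
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur == terminal_id:
            return True
        if cur in tree.splits:
            r = tree.splits[cur]
            stack.extend((r.low_child, r.high_child))
    return False


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator.

    ``node_occupancy`` maps terminal-node ids either to probabilities
    (summing to 1; membership is multinomial) or, with
    ``exact_occupancy=True``, to integer counts summing to ``n_subjects``.
    ``node_mortality`` gives each node's death probability; with
    ``deterministic_deaths=True`` exactly ``round(n_node * p_node)`` deaths
    are allocated per node, letting a configured cohort hit printed counts
    exactly rather than their Bernoulli neighborhoods.
    """

    n_subjects: int
    node_occupancy: Mapping[str, float]
    node_mortality: Mapping[str, float]
    seed: int = 0
    exact_occupancy: bool = False
    deterministic_deaths: bool = False
    prism_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PRISM_GAMMA)
    )
    los_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LOS_GAMMA)
    )
    organ_failure_params: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in ORGAN_FAILURE_PMF.items()}
    )
    of_day7_probs: Mapping[str, float] = field(default_factory=lambda: dict(OF_DAY7_PROB))
    comorbidity_prob: float = 0.38
    immune_suppression_prob: float = 0.09

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if set(self.node_occupancy) != set(self.node_mortality):
            raise ValueError("node_occupancy and node_mortality must cover the same nodes")
        occ = np.asarray(list(self.node_occupancy.values()), dtype=float)
        if np.any(occ < 0):
            raise ValueError("occupancy values must be non-negative")
        if self.exact_occupancy:
            if not np.all(occ == np.round(occ)) or int(occ.sum()) != self.n_subjects:
                raise ValueError(
                    "exact occupancy counts must be integers summing to n_subjects"
                )
        elif not math.isclose(float(occ.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("occupancy probabilities must sum to 1")
        for node, p in self.node_mortality.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"node_mortality[{node!r}] = {p} outside [0, 1]")


def cohort_2014_config(seed: int = 0) -> GeneratorConfig:
    """Configuration emulating the published test cohort (n = 182).

    Terminal occupancy puts 123 subjects in the low-risk nodes and 59 in
    the intermediate/high nodes; node-level observed mortality is set so
    the deterministic death allocation yields 4 low-risk deaths and 20
    intermediate/high deaths (24 total, 13.2% mortality), reproducing the
    published contingency table (TP 20, FP 39, TN 119, FN 4).
    """
    occupancy = {"TN1": 20, "TN2": 70, "TN3": 8, "TN4": 25,
                 "TN5": 13, "TN6": 14, "TN7": 28, "TN8": 4}
    deaths = {"TN1": 4, "TN2": 3, "TN3": 2, "TN4": 0,
              "TN5": 3, "TN6": 8, "TN7": 1, "TN8": 3}
    mortality = {k: deaths[k] / occupancy[k] for k in occupancy}
    return GeneratorConfig(
        n_subjects=182,
        node_occupancy=occupancy,
        node_mortality=mortality,
        seed=seed,
        exact_occupancy=True,
        deterministic_deaths=True,
    )


def _sample_interval(rng: np.random.Generator, iv: Interval, size: int) -> np.ndarray:
    lo, hi = iv.lower, iv.upper
    if lo == hi:
        return np.full(size, lo)
    if iv.lower_open:
        lo = np.nextafter(lo, hi)
    return rng.uniform(lo, hi, size=size)


def _sample_pmf(rng: np.random.Generator, pmf: Mapping[int, float], size: int) -> np.ndarray:
    values = np.asarray(sorted(pmf), dtype=int)
    probs = np.asarray([pmf[int(v)] for v in values], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(values, size=size, p=probs)


def generate_cohort(
    config: GeneratorConfig, tree: Optional[TreeSpec] = None
) -> list[CohortRecord]:
    """Draw a reproducible synthetic cohort under ``config``.

    Subjects are returned in a seed-determined shuffled order with ids
    S0001, S0002, ...  Every subject's biomarker/age vector lies strictly
    inside its generating terminal's admissible region, so classification
    round-trips exactly.
    """
    if tree is None:
        tree = load_default_tree()
    nodes = list(config.node_occupancy)
    unknown = [n for n in nodes if n not in tree.terminals]
    if unknown:
        raise ValueError(f"occupancy names unknown terminal nodes: {unknown}")
    base = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("membership", "biomarkers", "deaths", "prism", "course", "flags", "order"),
            base.spawn(7),
        )
    }

    # --- terminal-node membership -----------------------------------------
    if config.exact_occupancy:
        counts = {n: int(config.node_occupancy[n]) for n in nodes}
    else:
        probs = np.asarray([config.node_occupancy[n] for n in nodes], dtype=float)
        draw = streams["membership"].multinomial(config.n_subjects, probs)
        counts = {n: int(c) for n, c in zip(nodes, draw)}

    constraints = {n: path_constraints(tree, n) for n in nodes}

    node_of: list[str] = []
    profiles: list[BiomarkerProfile] = []
    died: list[bool] = []
    rng_bio = streams["biomarkers"]
    rng_death = streams["deaths"]
    for node in nodes:
        k = counts[node]
        if k == 0:
            continue
        iv = constraints[node].intervals
        cols = {
            var: _sample_interval(rng_bio, iv[var], k) for var in BIOMARKERS + ("age",)
        }
        for i in range(k):
            profiles.append(
                BiomarkerProfile(**{var: float(cols[var][i]) for var in BIOMARKERS + ("age",)})
            )
            node_of.append(node)
        p = config.node_mortality[node]
        if config.deterministic_deaths:
            n_dead = int(math.floor(k * p + 0.5))
            flags = np.zeros(k, dtype=bool)
            flags[rng_death.choice(k, size=n_dead, replace=False)] = True
        else:
            flags = rng_death.random(k) < p
        died.extend(bool(f) for f in flags)

    n = len(profiles)

    # --- severity and clinical course --------------------------------------
    died_arr = np.asarray(died, dtype=bool)
    prism = np.empty(n)
    rng_prism = streams["prism"]
    for label, mask in (("survivor", ~died_arr), ("nonsurvivor", died_arr)):
        shape, scale = config.prism_params[label]
        prism[mask] = np.round(rng_prism.gamma(shape, scale, size=int(mask.sum())))

    # Course group: deaths form one stratum; surviving subjects split by the
    # predicted risk class of their node (low -> "tn", else -> "fp").
    group = np.empty(n, dtype=object)
    for i in range(n):
        if died_arr[i]:
            group[i] = "died"
        else:
            group[i] = "tn" if tree.terminals[node_of[i]].risk_class == "low" else "fp"

    los = np.empty(n)
    mof = np.empty(n, dtype=int)
    of7 = np.empty(n, dtype=bool)
    rng_course = streams["course"]
    for label in ("tn", "fp", "died"):
        mask = group == label
        k = int(mask.sum())
        if k == 0:
            continue
        shape, scale = config.los_params[label]
        los[mask] = np.round(rng_course.gamma(shape, scale, size=k), 1)
        mof[mask] = _sample_pmf(rng_course, config.organ_failure_params[label], k)
        of7[mask] = rng_course.random(k) < config.of_day7_probs[label]

    rng_flags = streams["flags"]
    comorbid = rng_flags.random(n) < config.comorbidity_prob
    immune = rng_flags.random(n) < config.immune_suppression_prob

    order = streams["order"].permutation(n)
    records = []
    for rank, idx in enumerate(order, start=1):
        records.append(
            CohortRecord(
                subject_id=f"S{rank:04d}",
                profile=profiles[idx],
                died_28d=bool(died_arr[idx]),
                prism=float(prism[idx]),
                picu_los_days=float(los[idx]),
                max_organ_failures=int(mof[idx]),
                organ_failures_ge2_day7=bool(of7[idx]),
                comorbidity=bool(comorbid[idx]),
                immune_suppression=bool(immune[idx]),
            )
        )
    return records
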