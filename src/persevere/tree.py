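"""Fixed decision-tree risk model: biomarker/age vector -> mortality probability.

PERSEVERE (PEdiatRic SEpsis biomarkEr Risk modEl) is a CART-derived decision
tree that maps five serum biomarker concentrations (CCL3, IL8, HSPA1B, GZMB,
MMP8, all in pg/ml) plus age in years to one of eight terminal nodes, each
carrying an empirical 28-day mortality probability and a low / intermediate /
high risk class.  The tree is consumed here as *fixed parameters* — split
rules and terminal probabilities live in a versioned config file, never in
code — and applying it is a deterministic walk from the root to exactly one
terminal node.

Dichotomization uses a mortality-risk cut-off (default 2.5%): subjects whose
terminal-node probability exceeds the cut-off are predicted non-survivors;
everyone at or below it (i.e. the low-risk terminal nodes) is a predicted
survivor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "BIOMARKERS",
    "VARIABLES",
    "RISK_CLASSES",
    "DEFAULT_CUTOFF",
    "BiomarkerProfile",
    "SplitRule",
    "TerminalNode",
    "TreeSpec",
    "RiskAssignment",
    "TreeSpecError",
    "ProfileError",
    "risk_class_of",
    "load_tree_spec",
    "load_default_tree",
    "classify_subject",
    "classify_cohort",
    "risk_class_counts",
]

BIOMARKERS = ("ccl3", "il8", "hspa1b", "gzmb", "mmp8")
VARIABLES = BIOMARKERS + ("age",)
RISK_CLASSES = ("low", "intermediate", "high")

#: Mortality-risk cut-off dichotomizing predicted survivors vs non-survivors.
DEFAULT_CUTOFF = 0.025

# Risk-class probability bands.  The low band tops out at 0.025 (inclusive:
# a node at exactly 2.5% is low risk and its subjects predicted survivors);
# the published intermediate nodes span 0.182-0.267 and high nodes
# 0.472-0.625, so 0.40 is a safe interior boundary between the bands.
_LOW_MAX = 0.025
_HIGH_MIN = 0.40


class TreeSpecError(ValueError):
    """Raised for a structurally invalid tree specification."""


class ProfileError(ValueError):
    """Raised for an invalid biomarker/age input vector."""


def risk_class_of(probability: float) -> str:
    """Map a terminal-node mortality probability to its risk class.

    low: p <= 0.025; intermediate: 0.025 < p < 0.40; high: p >= 0.40.
    """
    if not (isinstance(probability, (int, float)) and math.isfinite(probability)):
        raise ValueError(f"mortality probability must be finite, got {probability!r}")
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"mortality probability {probability} outside [0, 1]")
    if probability <= _LOW_MAX:
        return "low"
    if probability < _HIGH_MIN:
        return "intermediate"
    return "high"


@dataclass(frozen=True)
class BiomarkerProfile:
    """One subject's serum biomarker panel (pg/ml) plus age (years)."""

    ccl3: float
    il8: float
    hspa1b: float
    gzmb: float
    mmp8: float
    age: float

    def __post_init__(self) -> None:
        for name in VARIABLES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ProfileError(f"{name}: expected a number, got {value!r}")
            if not math.isfinite(value):
                raise ProfileError(f"{name}: non-finite value {value!r}")
            if value < 0:
                raise ProfileError(f"{name}: negative value {value!r}")

    def value_of(self, variable: str) -> float:
        if variable not in VARIABLES:
            raise ProfileError(f"unknown decision variable {variable!r}")
        return float(getattr(self, variable))


@dataclass(frozen=True)
class SplitRule:
    """One internal decision rule: route on a single variable vs a threshold.

    ``op`` records the inequality direction as printed in the source figure so
    the transcription is lossless: with ``"<="`` (the default) a value equal to
    the threshold routes to ``low_child``; with ``"<"`` it routes to
    ``high_child``.
    """

    node_id: str
    variable: str
    threshold: float
    low_child: str
    high_child: str
    op: str = "<="

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise TreeSpecError(
                f"split {self.node_id}: unknown variable {self.variable!r}"
            )
        if not math.isfinite(self.threshold):
            raise TreeSpecError(f"split {self.node_id}: non-finite threshold")
        if self.op not in ("<=", "<"):
            raise TreeSpecError(f"split {self.node_id}: op must be '<=' or '<'")
        if self.low_child == self.node_id or self.high_child == self.node_id:
            raise TreeSpecError(f"split {self.node_id}: child equals parent")

    def goes_low(self, value: float) -> bool:
        """True if ``value`` routes to the low child."""
        if self.op == "<=":
            return value <= self.threshold
        return value < self.threshold


@dataclass(frozen=True)
class TerminalNode:
    """Leaf of the tree: a mortality probability and its risk class."""

    node_id: str
    mortality_probability: float
    risk_class: str = ""

    def __post_init__(self) -> None:
        p = self.mortality_probability
        if not (isinstance(p, (int, float)) and math.isfinite(p) and 0.0 <= p <= 1.0):
            raise TreeSpecError(
                f"terminal {self.node_id}: mortality probability {p!r} outside [0, 1]"
            )
        banded = risk_class_of(p)
        if not self.risk_class:
            object.__setattr__(self, "risk_class", banded)
        elif self.risk_class != banded:
            raise TreeSpecError(
                f"terminal {self.node_id}: declared risk class "
                f"{self.risk_class!r} inconsistent with probability {p} "
                f"(band says {banded!r})"
            )


@dataclass(frozen=True)
class TreeSpec:
    """A validated decision tree: split rules, terminal nodes, and a root."""

    splits: Mapping[str, SplitRule]
    terminals: Mapping[str, TerminalNode]
    root: str
    name: str = "unnamed"

    def __post_init__(self) -> None:
        overlap = set(self.splits) & set(self.terminals)
        if overlap:
            raise TreeSpecError(f"node ids used as both split and terminal: {sorted(overlap)}")
        all_ids = set(self.splits) | set(self.terminals)
        if self.root not in all_ids:
            raise TreeSpecError(f"root {self.root!r} is not a defined node")
        parents: dict[str, str] = {}
        for rule in self.splits.values():
            for child in (rule.low_child, rule.high_child):
                if child not in all_ids:
                    raise TreeSpecError(
                        f"split {rule.node_id}: child {child!r} is not defined"
                    )
                if child in parents:
                    raise TreeSpecError(
                        f"node {child!r} has two parents "
                        f"({parents[child]} and {rule.node_id})"
                    )
                parents[child] = rule.node_id
        if self.root in parents:
            raise TreeSpecError(f"root {self.root!r} has a parent ({parents[self.root]})")
        # Walk from the root; every node must be reached exactly once and the
        # walk must terminate (single-parent + full reachability excludes cycles).
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise TreeSpecError(f"cycle detected at node {node!r}")
            seen.add(node)
            if node in self.splits:
                rule = self.splits[node]
                stack.extend((rule.low_child, rule.high_child))
        unreachable = all_ids - seen
        if unreachable:
            raise TreeSpecError(f"unreachable nodes: {sorted(unreachable)}")

    @property
    def n_terminals(self) -> int:
        return len(self.terminals)

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def path_to(self, terminal_id: str) -> list[SplitRule]:
        """Split rules on the root-to-terminal path, in order."""
        if terminal_id not in self.terminals:
            raise TreeSpecError(f"unknown terminal {terminal_id!r}")
        parent_edge: dict[str, str] = {}
        for rule in self.splits.values():
            parent_edge[rule.low_child] = rule.node_id
            parent_edge[rule.high_child] = rule.node_id
        path: list[SplitRule] = []
        node = terminal_id
        while node != self.root:
            parent = parent_edge[node]
            path.append(self.splits[parent])
            node = parent
        path.reverse()
        return path


@dataclass(frozen=True)
class RiskAssignment:
    """Classification result for one subject."""

    subject_id: str
    terminal_node: str
    mortality_probability: float
    risk_class: str
    predicted_nonsurvivor: bool


def _parse_mapping(config: Mapping) -> TreeSpec:
    try:
        root = config["root"]
        split_items = config["splits"]
        terminal_items = config["terminals"]
    except KeyError as exc:
        raise TreeSpecError(f"tree config missing required key: {exc}") from None
    splits = {}
    for item in split_items:
        rule = SplitRule(
            node_id=str(item["node_id"]),
            variable=str(item["variable"]),
            threshold=float(item["threshold"]),
            low_child=str(item["low_child"]),
            high_child=str(item["high_child"]),
            op=str(item.get("op", "<=")),
        )
        if rule.node_id in splits:
            raise TreeSpecError(f"duplicate split node id {rule.node_id!r}")
        splits[rule.node_id] = rule
    terminals = {}
    for item in terminal_items:
        node = TerminalNode(
            node_id=str(item["node_id"]),
            mortality_probability=float(item["mortality_probability"]),
            risk_class=str(item.get("risk_class", "")),
        )
        if node.node_id in terminals:
            raise TreeSpecError(f"duplicate terminal node id {node.node_id!r}")
        terminals[node.node_id] = node
    return TreeSpec(
        splits=splits,
        terminals=terminals,
        root=str(root),
        name=str(config.get("name", "unnamed")),
    )


def load_tree_spec(source) -> TreeSpec:
    """Load and validate a tree specification.

    ``source`` may be a mapping already in memory, a path to a YAML/JSON
    file, or an open text stream.
    """
    if isinstance(source, Mapping):
        return _parse_mapping(source)
    if hasattr(source, "read"):
        return _parse_mapping(yaml.safe_load(source.read()))
    with open(source, "r", encoding="utf-8") as handle:
        return _parse_mapping(yaml.safe_load(handle.read()))


def load_default_tree() -> TreeSpec:
    """The packaged 2014 updated-model tree configuration."""
    ref = resources.files("persevere.data").joinpath("persevere_2014.yaml")
    return load_tree_spec(yaml.safe_load(ref.read_text(encoding="utf-8")))


def classify_subject(
    profile: BiomarkerProfile,
    tree: TreeSpec,
    cutoff: float = DEFAULT_CUTOFF,
    subject_id: str = "",
) -> RiskAssignment:
    """Walk the tree from the root to the unique terminal node for a profile.

    ``predicted_nonsurvivor`` is True iff the terminal probability strictly
    exceeds ``cutoff``; a probability exactly at the cut-off predicts survival.
    """
    node = tree.root
    while node in tree.splits:
        rule = tree.splits[node]
        value = profile.value_of(rule.variable)
        node = rule.low_child if rule.goes_low(value) else rule.high_child
    terminal = tree.terminals[node]
    return RiskAssignment(
        subject_id=subject_id,
        terminal_node=terminal.node_id,
        mortality_probability=terminal.mortality_probability,
        risk_class=terminal.risk_class,
        predicted_nonsurvivor=terminal.mortality_probability > cutoff,
    )


def classify_cohort(
    cohort: Sequence,
    tree: TreeSpec,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[RiskAssignment]:
    """Classify every record of a cohort, preserving order.

    Accepts any sequence of objects with ``subject_id`` and ``profile``
    attributes (e.g. :class:`persevere.cohort.CohortRecord`).  Records whose
    profiles fail validation are reported together, by subject id.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    assignments: list[RiskAssignment] = []
    bad: list[str] = []
    for record in cohort:
        try:
            assignments.append(
                classify_subject(
                    record.profile, tree, cutoff=cutoff, subject_id=record.subject_id
                )
            )
        except (ProfileError, AttributeError, TypeError):
            bad.append(str(record.subject_id))
    if bad:
        raise ProfileError(f"invalid biomarker profiles for subjects: {', '.join(bad)}")
    return assignments


def risk_class_counts(assignments: Iterable[RiskAssignment]) -> dict[str, int]:
    """Summary counts of assignments per risk class."""
    counts = {cls: 0 for cls in RISK_CLASSES}
    for a in assignments:
        counts[a.risk_class] += 1
    return counts
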