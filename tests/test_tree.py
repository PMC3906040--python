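"""Decision-tree model: validation, routing, banding, partition property."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from persevere.cohort import CohortRecord
from persevere.tree import (
    BIOMARKERS,
    BiomarkerProfile,
    ProfileError,
    TreeSpecError,
    classify_cohort,
    classify_subject,
    load_tree_spec,
    risk_class_of,
    risk_class_counts,
)

from conftest import enumerate_leaf_predicates


def make_profile(**over):
    base = dict(ccl3=10.0, il8=10.0, hspa1b=10.0, gzmb=1.0, mmp8=10.0, age=5.0)
    base.update(over)
    return BiomarkerProfile(**base)


class TestTreeSpecValidation:
    def test_default_tree_shape(self, tree):
        assert tree.n_terminals == 8
        assert tree.n_splits == 7
        variables = [r.variable for r in tree.splits.values()]
        assert variables.count("age") == 1
        assert sum(v != "age" for v in variables) == 6
        # one biomarker is reused on two branches
        assert len(set(variables)) < len(variables)

    def test_risk_classes_of_default_tree(self, tree):
        classes = {t.node_id: t.risk_class for t in tree.terminals.values()}
        assert {k for k, v in classes.items() if v == "low"} == {"TN2", "TN4", "TN7"}
        assert {k for k, v in classes.items() if v == "intermediate"} == {"TN1", "TN3", "TN5"}
        assert {k for k, v in classes.items() if v == "high"} == {"TN6", "TN8"}

    @pytest.mark.parametrize(
        "mutation, match",
        [
            (lambda c: c["splits"][0].update(low_child="NOPE"), "NOPE"),
            (lambda c: c["terminals"][0].update(mortality_probability=1.3), "outside"),
            (lambda c: c["splits"][0].update(variable="lactate"), "unknown variable"),
            (lambda c: c["splits"][0].update(high_child="N1"), "parent|cycle"),
        ],
    )
    def test_malformed_configs_rejected(self, tree, mutation, match):
        config = {
            "root": tree.root,
            "splits": [
                dict(node_id=r.node_id, variable=r.variable, threshold=r.threshold,
                     low_child=r.low_child, high_child=r.high_child, op=r.op)
                for r in tree.splits.values()
            ],
            "terminals": [
                dict(node_id=t.node_id, mortality_probability=t.mortality_probability)
                for t in tree.terminals.values()
            ],
        }
        mutation(config)
        with pytest.raises(TreeSpecError, match=match):
            load_tree_spec(config)

    def test_declared_class_must_match_band(self, tree):
        config = {
            "root": "T",
            "splits": [],
            "terminals": [dict(node_id="T", mortality_probability=0.5, risk_class="low")],
        }
        with pytest.raises(TreeSpecError, match="inconsistent"):
            load_tree_spec(config)


class TestRiskClassBanding:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0, "low"), (0.025, "low"), (0.0251, "intermediate"),
         (0.182, "intermediate"), (0.267, "intermediate"),
         (0.40, "high"), (0.472, "high"), (0.625, "high"), (1.0, "high")],
    )
    def test_bands(self, p, expected):
        assert risk_class_of(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.1, float("nan")])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            risk_class_of(p)


class TestClassifySubject:
    def test_boundary_value_routes_low(self, tree):
        root = tree.splits[tree.root]
        at = make_profile(**{root.variable: root.threshold})
        above = make_profile(**{root.variable: root.threshold * (1 + 1e-9)})
        low_side = classify_subject(at, tree)
        high_side = classify_subject(above, tree)
        low_leaves = {t for t, preds in _leaves_below(tree, root.low_child)}
        assert low_side.terminal_node in low_leaves
        assert high_side.terminal_node not in low_leaves

    def test_low_risk_profile_is_predicted_survivor(self, tree):
        # Satisfies every constraint on the path to TN2 (mortality 0.000):
        # low CCL3, low HSPA1B, high GZMB.
        profile = make_profile(ccl3=10.0, hspa1b=100.0, gzmb=100.0)
        a = classify_subject(profile, tree)
        assert a.terminal_node == "TN2"
        assert a.risk_class == "low"
        assert not a.predicted_nonsurvivor

    def test_cutoff_tie_predicts_survivor(self, tree):
        # TN7 sits exactly at the 2.5% cut-off: still a predicted survivor.
        profile = make_profile(ccl3=500.0, mmp8=60000.0, gzmb=5.0)
        a = classify_subject(profile, tree)
        assert a.terminal_node == "TN7"
        assert a.mortality_probability == 0.025
        assert not a.predicted_nonsurvivor
        # while any probability strictly above the cut-off predicts death
        high = classify_subject(make_profile(ccl3=500.0, mmp8=60000.0, gzmb=50.0), tree)
        assert high.terminal_node == "TN8"
        assert high.predicted_nonsurvivor

    def test_invalid_profile_named(self):
        with pytest.raises(ProfileError, match="gzmb"):
            make_profile(gzmb=-1.0)
        with pytest.raises(ProfileError, match="il8"):
            make_profile(il8=float("nan"))

    def test_determinism(self, tree):
        p = make_profile(ccl3=200.0, mmp8=50000.0, gzmb=20.0)
        a1 = classify_subject(p, tree)
        a2 = classify_subject(p, tree)
        assert a1 == a2


def _leaves_below(tree, node):
    preds = enumerate_leaf_predicates(tree)
    out = []
    for leaf in preds:
        cur = leaf
        parents = {}
        for r in tree.splits.values():
            parents[r.low_child] = r.node_id
            parents[r.high_child] = r.node_id
        chain = {leaf}
        while cur in parents:
            cur = parents[cur]
            chain.add(cur)
        if node in chain:
            out.append((leaf, preds[leaf]))
    return out


class TestPartitionProperty:
    def test_lattice_partition_matches_path_oracle(self, tree):
        """Threshold-adjacent lattice: every cell belongs to exactly one leaf,
        and the classifier agrees with independent path-predicate evaluation."""
        leaf_preds = enumerate_leaf_predicates(tree)
        grids = {}
        for var in BIOMARKERS + ("age",):
            ts = sorted({r.threshold for r in tree.splits.values() if r.variable == var})
            points = [0.0]
            for t in ts:
                points += [t * 0.5, t, t * (1 + 1e-9), t * 2]
            grids[var] = sorted(set(points)) or [0.0, 1.0]
        names = BIOMARKERS + ("age",)
        count = 0
        for combo in itertools.product(*(grids[v] for v in names)):
            values = dict(zip(names, combo))
            matches = [
                leaf for leaf, preds in leaf_preds.items()
                if all(p(values) for p in preds)
            ]
            assert len(matches) == 1, f"profile {values} matched {matches}"
            assigned = classify_subject(BiomarkerProfile(**values), tree)
            assert assigned.terminal_node == matches[0]
            count += 1
        assert count > 1000  # the lattice genuinely covers the split structure

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(0, 5e6, allow_nan=False) for _ in range(5)]),
        st.floats(0, 18, allow_nan=False),
    )
    def test_random_profiles_reach_exactly_one_leaf(self, biomarkers, age):
        from persevere.tree import load_default_tree

        tree = load_default_tree()
        leaf_preds = enumerate_leaf_predicates(tree)
        values = dict(zip(BIOMARKERS, biomarkers))
        values["age"] = age
        matches = [l for l, preds in leaf_preds.items() if all(p(values) for p in preds)]
        assert len(matches) == 1
        assert classify_subject(BiomarkerProfile(**values), tree).terminal_node == matches[0]


class TestClassifyCohort:
    def test_counts_and_order(self, tree, emulated_cohort, emulated_assignments):
        assert len(emulated_assignments) == 182
        assert [a.subject_id for a in emulated_assignments] == [
            r.subject_id for r in emulated_cohort
        ]
        counts = risk_class_counts(emulated_assignments)
        assert counts["low"] == 123
        assert counts["intermediate"] + counts["high"] == 59
        predicted_dead = sum(a.predicted_nonsurvivor for a in emulated_assignments)
        assert predicted_dead == 59

    def test_empty_cohort_rejected(self, tree):
        with pytest.raises(ValueError, match="empty"):
            classify_cohort([], tree)

    def test_invalid_record_lists_subject_ids(self, tree):
        class Raw:
            pass

        good = CohortRecord("ok", make_profile(), died_28d=False)
        bad = Raw()
        bad.subject_id = "bad1"
        bad.profile = None
        records = [good, bad]
        with pytest.raises(ProfileError, match="bad1"):
            classify_cohort(records, tree)
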