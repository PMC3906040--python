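import pytest

from persevere.simulate import generate_cohort, cohort_2014_config
from persevere.tree import classify_cohort, load_default_tree


@pytest.fixture(scope="session")
def tree():
    return load_default_tree()


@pytest.fixture(scope="session")
def emulated_cohort(tree):
    """The deterministic test-cohort emulation: n=182, 24 deaths, 123 low risk."""
    return generate_cohort(cohort_2014_config(seed=7), tree)


@pytest.fixture(scope="session")
def emulated_assignments(tree, emulated_cohort):
    return classify_cohort(emulated_cohort, tree)


def enumerate_leaf_predicates(tree):
    """Test-local oracle: every root-to-leaf path as a list of predicates.

    Built by recursive descent over the raw split rules, independently of
    the classifier's walk loop.
    """
    paths = {}

    def descend(node, preds):
        if node in tree.terminals:
            paths[node] = preds
            return
        rule = tree.splits[node]

        def low(v, r=rule):
            x = v[r.variable]
            return x <= r.threshold if r.op == "<=" else x < r.threshold

        def high(v, r=rule):
            x = v[r.variable]
            return x > r.threshold if r.op == "<=" else x >= r.threshold

        descend(rule.low_child, preds + [low])
        descend(rule.high_child, preds + [high])

    descend(tree.root, [])
    return paths
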