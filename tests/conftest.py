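"""Shared fixtures and oracle helpers for the test suite."""

import itertools
import math

import numpy as np
import pytest

import paleophylo as pp
from paleophylo.discrete import MkModel, transition_probs
from paleophylo.trees import Node, TimeTree


def random_timetree(rng, n_tips, fossil_prob=0.4):
    """Random binary time tree with a mix of extant and fossil tips."""
    tree = pp.yule_tree(n_tips, rng)
    for tip in tree.tips():
        if rng.random() < fossil_prob:
            tip.age = float(rng.uniform(0.0, 0.8)) * tip.parent.age
    tree.index_nodes()
    tree.validate()
    return tree


def brute_force_mk(tree, char, model):
    """Exhaustive enumeration oracle for the Mk likelihood and per-node
    marginals: sums the joint probability over every assignment of
    internal-node states under a uniform root prior."""
    nodes = list(tree.preorder())
    internals = [n for n in nodes if not n.is_leaf]
    k = model.k
    P = {}
    for n in nodes:
        if n.parent is not None:
            P[n.id] = transition_probs(model, n.parent.age - n.age)
    total = 0.0
    marg = {n.id: np.zeros(k) for n in nodes}
    tip_state = {}
    tip_choices = []
    tips = tree.tips()
    for t in tips:
        s = char[t.label]
        tip_choices.append(range(k) if s is None else [s])
    for tip_assign in itertools.product(*tip_choices):
        for t, s in zip(tips, tip_assign):
            tip_state[t.id] = s
        for assign in itertools.product(range(k), repeat=len(internals)):
            amap = {n.id: s for n, s in zip(internals, assign)}
            amap.update(tip_state)
            pr = 1.0 / k
            for parent, child in tree.branch_iter():
                pr *= P[child.id][amap[parent.id], amap[child.id]]
            total += pr
            for n in nodes:
                marg[n.id][amap[n.id]] += pr
    for n in nodes:
        marg[n.id] /= total
    return math.log(total), marg


def brute_force_hdi(samples, mass):
    """Check every contiguous window of sorted samples for the shortest
    one holding ceil(mass * n) points."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(math.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, float(x[i]), float(x[i + m - 1]))
    return best[1], best[2]


@pytest.fixture(scope="session")
def dataset():
    """One synthetic study shared across read-only tests."""
    return pp.generate_dataset(pp.SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def cherry_tree():
    """Two tips with branch durations 1 and 3."""
    root = Node(None, 3.0)
    root.add_child(Node("A", 2.0))
    root.add_child(Node("B", 0.0))
    return TimeTree(root)


@pytest.fixture
def six_tip_fossil_tree():
    """Hand-built 6-tip tree with two fossil tips, for manual tallies.

    Root at 10; internal nodes at 8, 6, 4; fossil tips F1 (age 5) and
    F2 (age 3); extant tips A-D at 0.
    """
    root = Node(None, 10.0)
    n8 = root.add_child(Node(None, 8.0))
    f1 = root.add_child(Node("F1", 5.0))
    n6 = n8.add_child(Node(None, 6.0))
    a = n8.add_child(Node("A", 0.0))
    n4 = n6.add_child(Node(None, 4.0))
    f2 = n6.add_child(Node("F2", 3.0))
    b = n4.add_child(Node("B", 0.0))
    c = n4.add_child(Node("C", 0.0))
    d = root.add_child(Node("D", 0.0))
    tree = TimeTree(root)
    tree.validate()
    return tree
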