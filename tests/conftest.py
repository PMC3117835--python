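"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

import stemevol as se


def brute_force_parsimony(tree, leaf_states: dict[str, str], states) -> float:
    """Exhaustive minimum number of changes over all internal labelings.

    Independent of the Sankoff implementation: enumerates every assignment
    of states to internal nodes and counts mismatched edges directly.
    Feasible for <= ~6 leaves.
    """
    internals = [n for n in tree.nodes if not n.is_leaf]
    edges = [(n.parent.id, n.id) for n in tree.nodes if n.parent is not None]
    fixed = {lf.id: leaf_states[lf.name] for lf in tree.leaves}
    best = float("inf")
    for assign in product(states, repeat=len(internals)):
        label = dict(fixed)
        label.update({n.id: s for n, s in zip(internals, assign)})
        cost = sum(1 for a, b in edges if label[a] != label[b])
        best = min(best, cost)
    return float(best)


def fitch_count(tree, leaf_states: dict[str, str]) -> float:
    """Classic Fitch parsimony count for strictly binary trees."""
    changes = 0

    def down(node):
        nonlocal changes
        if node.is_leaf:
            return {leaf_states[node.name]}
        sets = [down(c) for c in node.children]
        assert len(sets) == 2, "Fitch oracle requires a binary tree"
        inter = sets[0] & sets[1]
        if inter:
            return inter
        changes += 1
        return sets[0] | sets[1]

    down(tree.root)
    return float(changes)


def random_tree_with_polytomies(n_leaves: int, rng) -> se.PhyloTree:
    """Random topology in which some internal nodes are multifurcating."""
    tree = se.random_tree(n_leaves, rng=rng)

    def collapse(node):
        new_children = []
        for child in list(node.children):
            collapse(child)
            if not child.is_leaf and rng.random() < 0.3:
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = []
        for c in new_children:
            node.add(c)

    collapse(tree.root)
    return se.PhyloTree(tree.root)


@pytest.fixture
def small_alignment():
    """Two hairpins, one species with a broken pair, one fully gapped stem."""
    return se.StructuralAlignment(
        ids=["sp1", "sp2", "sp3", "sp4"],
        rows=[
            "GGGAAACCCUUGCAAAGC",
            "GGGAAACCCUUGCAAAGC",
            "GGAAAACCCUUGCAAAGC",
            "GGGAAACCCUU------C",
        ],
        consensus_structure="(((...)))..((...))",
        family_label="toy",
    )


@pytest.fixture
def default_sim():
    """One default-rate simulated family, fixed seed."""
    return se.simulate_family(se.EvolutionConfig(seed=11), n_leaves=12)
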