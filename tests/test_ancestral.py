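"""Parsimony reconstructions against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

import stemevol as se
from stemevol.alphabet import STATES
from stemevol.errors import MappingError, MissingDataError

from conftest import brute_force_parsimony, fitch_count, random_tree_with_polytomies


class TestSquaredChange:
    def test_star_tree_constant_values(self):
        t = se.PhyloTree.from_newick("(A,B,C,D);")
        r = se.squared_change_parsimony(t, {n: 5.0 for n in "ABCD"})
        assert r.cost == 0.0
        assert all(v == pytest.approx(5.0) for v in r.values.values())

    def test_cherry_midpoint(self):
        t = se.PhyloTree.from_newick("(A,B);")
        r = se.squared_change_parsimony(t, {"A": 0.0, "B": 6.0})
        assert r.values[t.root.id] == pytest.approx(3.0)
        assert r.cost == pytest.approx(18.0)

    def test_leaf_values_fixed_to_observations(self):
        t = se.PhyloTree.from_newick("((A,B),(C,D));")
        vals = {"A": 1.0, "B": 2.0, "C": 7.0, "D": 4.0}
        r = se.squared_change_parsimony(t, vals)
        for leaf in t.leaves:
            assert r.values[leaf.id] == vals[leaf.name]

    def test_missing_leaf_named_in_error(self):
        t = se.PhyloTree.from_newick("(A,B);")
        with pytest.raises(MissingDataError, match="B"):
            se.squared_change_parsimony(t, {"A": 1.0})

    def test_matches_numerical_optimizer_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            tree = random_tree_with_polytomies(8, rng)
            vals = {n: float(rng.integers(0, 10)) for n in tree.leaf_names}
            rec = se.squared_change_parsimony(tree, vals)
            internals = [n for n in tree.nodes if not n.is_leaf]
            edges = [(n.parent.id, n.id) for n in tree.nodes if n.parent]
            leaf_vals = {lf.id: vals[lf.name] for lf in tree.leaves}

            def objective(x, internals=internals, edges=edges, leaf_vals=leaf_vals):
                v = dict(leaf_vals)
                v.update({n.id: xi for n, xi in zip(internals, x)})
                return sum((v[a] - v[b]) ** 2 for a, b in edges)

            opt = minimize(objective, np.zeros(len(internals)), method="BFGS")
            assert rec.cost == pytest.approx(opt.fun, rel=1e-6, abs=1e-9)

    def test_polytomy_child_order_irrelevant(self):
        t1 = se.PhyloTree.from_newick("((A,B,C),D);")
        t2 = se.PhyloTree.from_newick("((C,A,B),D);")
        vals = {"A": 1.0, "B": 4.0, "C": 9.0, "D": 0.0}
        assert se.squared_change_parsimony(t1, vals).cost == pytest.approx(
            se.squared_change_parsimony(t2, vals).cost
        )


def _column_alignment(states: dict[str, str]) -> se.StructuralAlignment:
    ids = sorted(states)
    return se.StructuralAlignment(
        ids=ids, rows=[states[i] for i in ids], consensus_structure="."
    )


class TestSequenceParsimony:
    def test_constant_column_zero_changes(self):
        t = se.PhyloTree.from_newick("((A,B),(C,D));")
        anc = se.parsimony_ancestral_sequences(
            t, _column_alignment({n: "A" for n in "ABCD"})
        )
        assert anc.score == 0
        assert anc.sequences[t.root.id] == "A"

    def test_balanced_split_root_ambiguous(self):
        t = se.PhyloTree.from_newick("((A,B),(C,D));")
        anc = se.parsimony_ancestral_sequences(
            t, _column_alignment({"A": "A", "B": "A", "C": "C", "D": "C"})
        )
        assert anc.score == 1
        assert anc.sequences[t.root.id] == "?"
        assert anc.ambiguous[t.root.id][0] == ["A", "C"]
        # brute force confirms the minimum
        assert brute_force_parsimony(
            t, {"A": "A", "B": "A", "C": "C", "D": "C"}, STATES
        ) == 1

    def test_matches_exhaustive_minimum_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            tree = random_tree_with_polytomies(n, rng)
            states = {
                name: STATES[rng.integers(5)] for name in tree.leaf_names
            }
            anc = se.parsimony_ancestral_sequences(tree, _column_alignment(states))
            assert anc.score == brute_force_parsimony(tree, states, STATES)

    def test_binary_tree_score_equals_fitch(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = se.random_tree(int(rng.integers(3, 9)), rng=rng)
            states = {name: STATES[rng.integers(5)] for name in tree.leaf_names}
            anc = se.parsimony_ancestral_sequences(tree, _column_alignment(states))
            assert anc.score == fitch_count(tree, states)

    def test_unsequenced_leaf_contributes_no_cost(self):
        t = se.PhyloTree.from_newick("((A,B),(C,D));")
        anc = se.parsimony_ancestral_sequences(
            t, _column_alignment({"A": "G", "B": "G", "C": "G", "D": "~"})
        )
        assert anc.score == 0
        assert anc.sequences[t.root.id] == "G"

    def test_gap_is_a_reconstructable_state(self):
        t = se.PhyloTree.from_newick("((A,B),((C,D),E));")
        states = {"A": "-", "B": "-", "C": "-", "D": "-", "E": "A"}
        anc = se.parsimony_ancestral_sequences(t, _column_alignment(states))
        assert anc.score == 1
        assert anc.sequences[t.root.id] == "-"

    def test_gaps_as_missing_switch(self):
        t = se.PhyloTree.from_newick("((A,B),C);")
        states = {"A": "G", "B": "-", "C": "G"}
        strict = se.parsimony_ancestral_sequences(t, _column_alignment(states))
        lenient = se.parsimony_ancestral_sequences(
            t, _column_alignment(states), gaps_as_missing=True
        )
        assert strict.score == 1 and lenient.score == 0

    def test_duplicated_leaf_never_raises_score(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tree = se.random_tree(5, rng=rng)
            states = {name: STATES[rng.integers(5)] for name in tree.leaf_names}
            base = se.parsimony_ancestral_sequences(
                tree, _column_alignment(states)
            ).score
            # duplicate one leaf as its own sister
            grown = se.PhyloTree.from_newick(tree.to_newick())
            leaf = grown.leaves[0]
            twin_states = dict(states)
            twin_states[leaf.name + "_twin"] = states[leaf.name]
            child_a = se.tree.Node(leaf.name)
            child_b = se.tree.Node(leaf.name + "_twin")
            leaf.name = None
            leaf.add(child_a)
            leaf.add(child_b)
            grown = se.PhyloTree(grown.root)
            score = se.parsimony_ancestral_sequences(
                grown, _column_alignment(twin_states)
            ).score
            assert score <= base + 0  # identical neighbor adds no changes
            assert score == base

    def test_leaf_missing_from_alignment_is_mapping_error(self):
        t = se.PhyloTree.from_newick("(A,B);")
        with pytest.raises(MappingError):
            se.parsimony_ancestral_sequences(t, _column_alignment({"A": "A"}))


class TestPresence:
    def test_all_present(self):
        t = se.PhyloTree.from_newick("((A,B),C);")
        r = se.presence_reconstruction(t, {n: "present" for n in "ABC"})
        assert r.states[t.root.id] == "present"
        assert r.cost == 0

    def test_symmetric_cherry_unresolved(self):
        t = se.PhyloTree.from_newick("(A,B);")
        r = se.presence_reconstruction(t, {"A": "present", "B": "absent"})
        assert r.states[t.root.id] == "unresolved"

    def test_clade_specific_stem_absent_at_root(self):
        # present only within one derived clade -> root reconstructed absent
        t = se.PhyloTree.from_newick("(((m1,m2),(o1,o2)),(o3,(o4,o5)));")
        obs = {n: "absent" for n in ["o1", "o2", "o3", "o4", "o5"]}
        obs.update({"m1": "present", "m2": "present"})
        r = se.presence_reconstruction(t, obs)
        assert r.states[t.root.id] == "absent"

    def test_unknown_leaves_do_not_constrain(self):
        t = se.PhyloTree.from_newick("((A,B),C);")
        r = se.presence_reconstruction(
            t, {"A": "present", "B": "present", "C": "unknown"}
        )
        assert r.states[t.root.id] == "present"


def test_pruning_unknown_leaves_never_increases_cost():
    rng = np.random.default_rng(19)
    for _ in range(10):
        tree = se.random_tree(6, rng=rng)
        states = {name: STATES[rng.integers(5)] for name in tree.leaf_names}
        full = se.parsimony_ancestral_sequences(
            tree, _column_alignment(states)
        ).score
        drop = tree.leaf_names[int(rng.integers(6))]
        pruned = tree.prune_to(set(tree.leaf_names) - {drop})
        sub = {k: v for k, v in states.items() if k != drop}
        reduced = se.parsimony_ancestral_sequences(
            pruned, _column_alignment(sub)
        ).score
        assert reduced <= full
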