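"""Majority-rule consensus and exact character optimization."""
import itertools

import numpy as np
import pytest

from areagram import PresenceMatrix, majority_consensus, optimize_characters
from areagram.consensus import consensus_length
from areagram.parsimony import TreeSet
from areagram.trees import AreaTree

from conftest import random_binary_tree, random_matrix


def _treeset(adjs, labels):
    trees = [AreaTree(a, labels) for a in adjs]
    return TreeSet(trees=trees, length=0, per_character_steps=[])


class TestMajorityRule:
    def test_consensus_of_identical_trees_is_that_tree(self):
        labels = [f"A{i}" for i in range(6)]
        adj = random_binary_tree(6, seed=1)
        ts = _treeset([adj, dict(adj), dict(adj)], labels)
        cons = majority_consensus(ts)
        tree = AreaTree(adj, labels)
        assert cons.clades() - {frozenset(labels[1:])} == tree.clades("A0") - {
            frozenset(labels[1:])
        }
        assert all(nd.frequency == 1.0 for nd in cons.internal_nodes())

    def test_two_thirds_clade_kept_minority_dropped(self):
        labels = ["A0", "A1", "A2", "A3", "A4"]
        # two trees share ((A1,A2)); the third groups ((A1,A3)) instead
        t12 = AreaTree.from_newick("(A0,((A1,A2),A3,A4));", labels)
        t3 = AreaTree.from_newick("(A0,((A1,A3),A2,A4));", labels)
        ts = TreeSet(trees=[t12, t12, t3], length=0, per_character_steps=[])
        cons = majority_consensus(ts)
        assert frozenset({"A1", "A2"}) in cons.clades()
        assert frozenset({"A1", "A3"}) not in cons.clades()
        node = next(
            nd for nd in cons.internal_nodes() if nd.leaves == frozenset({"A1", "A2"})
        )
        assert node.frequency == pytest.approx(2 / 3)

    def test_exactly_half_is_dropped_under_strict_majority(self):
        labels = ["A0", "A1", "A2", "A3", "A4"]
        t1 = AreaTree.from_newick("(A0,((A1,A2),A3,A4));", labels)
        t2 = AreaTree.from_newick("(A0,((A1,A3),A2,A4));", labels)
        ts = TreeSet(trees=[t1, t2], length=0, per_character_steps=[])
        cons = majority_consensus(ts)
        assert cons.clades() == {frozenset({"A1", "A2", "A3", "A4"})}

    def test_consensus_clades_subset_of_input_clades(self, pae_trees):
        cons = majority_consensus(pae_trees)
        all_input = set().union(*(t.clades("Outgroup") for t in pae_trees.trees))
        ingroup = frozenset(pae_trees.trees[0].labels) - {"Outgroup"}
        assert cons.clades() - {ingroup} <= all_input

    def test_leaf_set_mismatch_rejected(self):
        a = AreaTree.from_newick("(A0,(A1,(A2,A3)));", ["A0", "A1", "A2", "A3"])
        b = AreaTree.from_newick("(A0,(A1,(A2,B3)));", ["A0", "A1", "A2", "B3"])
        ts = TreeSet(trees=[a, b], length=0, per_character_steps=[])
        with pytest.raises(ValueError, match="leaf"):
            majority_consensus(ts)


def _brute_optimal_assignments(cons, matrix, char):
    """Enumerate all internal-state assignments of the rooted consensus
    (outgroup fixed at 0) and keep the minimum-change ones."""
    internal = cons.internal_nodes()
    leaves = [nd for nd in cons.nodes() if nd.is_leaf]
    col = matrix.data[char]
    parent = {}
    for nd in cons.nodes():
        for c in nd.children:
            parent[id(c)] = nd
    best, opt = None, []
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = {id(nd): s for nd, s in zip(internal, assign)}
        for lf in leaves:
            st[id(lf)] = int(col[lf.label])
        cost = sum(
            1 for nd in cons.nodes() if nd is not cons.root
            and st[id(nd)] != st[id(parent[id(nd)])]
        )
        cost += 1 if st[id(cons.root)] != 0 else 0  # outgroup branch
        if best is None or cost < best:
            best, opt = cost, []
        if cost == best:
            opt.append(dict(st))
    return best, opt, parent


class TestOptimization:
    def test_clade_restricted_character_is_unambiguous_gain(self):
        labels = ["OG", "W", "X", "Y", "Z"]
        vals = np.array([[0], [0], [0], [1], [1]])
        m = PresenceMatrix.from_arrays(labels, ["c"], vals, outgroup="OG")
        t = AreaTree.from_newick("(OG,((Y,Z),W,X));", labels)
        cons = majority_consensus(TreeSet(trees=[t], length=0, per_character_steps=[]))
        optimize_characters(cons, m)
        node = next(nd for nd in cons.internal_nodes() if nd.leaves == {"Y", "Z"})
        assert ("c", "gain", False) in node.changes

    def test_single_area_character_gains_on_terminal_branch(self):
        labels = ["OG", "W", "X", "Y"]
        vals = np.array([[0], [0], [1], [0]])
        m = PresenceMatrix.from_arrays(labels, ["c"], vals, outgroup="OG")
        t = AreaTree.from_newick("(OG,(W,X,Y));", labels)
        cons = majority_consensus(TreeSet(trees=[t], length=0, per_character_steps=[]))
        optimize_characters(cons, m)
        leaf = next(nd for nd in cons.nodes() if nd.label == "X")
        assert ("c", "gain", False) in leaf.changes

    def test_gain_classification_matches_exhaustive_mpr_enumeration(self):
        """Unambiguous-gain calls equal brute-force enumeration of every
        most-parsimonious reconstruction on random trees."""
        for seed in range(12):
            m = random_matrix(6, 4, seed=500 + seed)
            adj = random_binary_tree(6, seed=seed, polytomy_prob=0.3)
            t = AreaTree(adj, m.areas)
            cons = majority_consensus(
                TreeSet(trees=[t], length=0, per_character_steps=[])
            )
            optimize_characters(cons, m)
            for char in m.characters:
                best, opt, parent = _brute_optimal_assignments(cons, m, char)
                for nd in cons.nodes():
                    if nd is cons.root:
                        continue
                    par = parent[id(nd)]
                    pairs = {(st[id(par)], st[id(nd)]) for st in opt}
                    recorded = {c for c in nd.changes if c[0] == char}
                    if pairs == {(0, 1)}:
                        assert (char, "gain", False) in recorded
                    elif pairs == {(1, 0)}:
                        assert (char, "loss", False) in recorded
                    elif (0, 1) in pairs or (1, 0) in pairs:
                        assert recorded and all(c[2] for c in recorded)
                    else:
                        assert not recorded

    def test_consensus_steps_at_least_optimal_length(self, pae_trees):
        from areagram import datasets

        m = datasets.load_province_matrix()
        cons = majority_consensus(pae_trees)
        assert consensus_length(cons, m) >= pae_trees.length
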