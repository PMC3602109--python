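"""Parsimony engine: scoring, searches, collapse, statistics."""
import numpy as np
import pytest

from areagram import (
    PresenceMatrix,
    SearchConfig,
    branch_and_bound,
    collapse_tree,
    exhaustive_search,
    heuristic_search,
    tree_length,
    tree_stats,
)
from areagram.parsimony import (
    display_round,
    fitch_length,
    pack_matrix,
    per_character_steps,
)
from areagram.trees import AreaTree, split_signature

from conftest import brute_force_length, random_binary_tree, random_matrix


class TestScoring:
    def test_matches_exhaustive_state_assignment_oracle(self):
        """Fitch/Hartigan length equals brute-force enumeration of all
        internal state assignments, on binary and polytomous trees."""
        for trial in range(30):
            n = 4 + trial % 3  # 4..6 leaves
            m = random_matrix(n, 5, seed=trial)
            ls, nc = pack_matrix(m)
            adj = random_binary_tree(n, seed=trial, polytomy_prob=0.4 * (trial % 2))
            got = fitch_length(adj, n, ls, nc)
            want = brute_force_length(adj, n, m.values())
            assert got == want, f"trial {trial}"

    def test_all_zero_matrix_scores_zero(self):
        vals = np.zeros((5, 4), dtype=int)
        m = PresenceMatrix.from_arrays(
            [f"A{i}" for i in range(5)], list("wxyz"), vals, outgroup="A0"
        )
        ls, nc = pack_matrix(m)
        adj = random_binary_tree(5, seed=0)
        assert fitch_length(adj, 5, ls, nc) == 0

    def test_per_character_steps_sum_to_length(self):
        m = random_matrix(7, 6, seed=3)
        ls, nc = pack_matrix(m)
        adj = random_binary_tree(7, seed=3)
        steps = per_character_steps(adj, 7, ls, nc)
        assert sum(steps) == fitch_length(adj, 7, ls, nc)

    def test_invariant_to_area_order(self):
        """Scoring a tree against a matrix must not depend on row order."""
        m = random_matrix(6, 5, seed=11)
        ls, nc = pack_matrix(m)
        adj = random_binary_tree(6, seed=11)
        tree = AreaTree(adj, m.areas)
        L1, _ = tree_length(m, tree)
        perm = m.data.iloc[[0, 3, 1, 5, 2, 4]]
        m2 = PresenceMatrix(perm, outgroup="A0")
        L2, _ = tree_length(m2, tree)
        assert L1 == L2 == fitch_length(adj, 6, ls, nc)


class TestExactSearch:
    def test_two_state_split_groups_the_shared_state(self):
        vals = np.array([[0, ], [0, ], [1, ], [1, ]])
        m = PresenceMatrix.from_arrays(["A0", "A1", "B0", "B1"], ["c"], vals, outgroup="A0")
        ts = branch_and_bound(m)
        assert ts.length == 1
        # the single informative split groups the two presence areas
        assert ts.n_trees == 1
        assert frozenset({"B0", "B1"}) in ts.trees[0].clades("A0")

    def test_branch_and_bound_equals_exhaustive_enumeration(self):
        for seed in range(10):
            m = random_matrix(7, 8, seed=100 + seed)
            bb = branch_and_bound(m)
            ex = exhaustive_search(m)
            assert bb.length == ex.length
            assert {t.splits() for t in bb.trees} == {t.splits() for t in ex.trees}

    def test_branch_and_bound_refuses_large_matrices(self):
        m = random_matrix(16, 4, seed=0)
        with pytest.raises(ValueError, match="14"):
            branch_and_bound(m)


class TestHeuristicSearch:
    def test_single_character_any_topology_length_one(self):
        vals = np.zeros((5, 1), dtype=int)
        vals[2, 0] = 1
        m = PresenceMatrix.from_arrays(
            [f"A{i}" for i in range(5)], ["c"], vals, outgroup="A0"
        )
        ts = heuristic_search(m, SearchConfig(replicates=2, seed=0))
        assert ts.length == 1

    def test_matches_branch_and_bound_on_random_matrices(self):
        for seed in range(10):
            m = random_matrix(8, 10, seed=200 + seed)
            hs = heuristic_search(m, SearchConfig(replicates=3, seed=seed))
            bb = branch_and_bound(m)
            assert hs.length == bb.length
            assert {t.splits() for t in hs.trees} == {t.splits() for t in bb.trees}

    def test_same_seed_reproduces_identical_tree_set(self):
        m = random_matrix(9, 8, seed=42)
        cfg = SearchConfig(replicates=5, seed=7)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert a.length == b.length
        assert a.to_newick("A0") == b.to_newick("A0")

    def test_best_length_bounds_any_user_tree(self):
        m = random_matrix(8, 10, seed=5)
        hs = heuristic_search(m, SearchConfig(replicates=3, seed=5))
        ls, nc = pack_matrix(m)
        for seed in range(5):
            adj = random_binary_tree(8, seed=seed)
            assert hs.length <= fitch_length(adj, 8, ls, nc)

    def test_ratchet_reaches_same_optimum(self):
        m = random_matrix(8, 10, seed=77)
        plain = heuristic_search(m, SearchConfig(replicates=3, seed=1))
        ratch = heuristic_search(
            m, SearchConfig(replicates=2, seed=1, ratchet=True, ratchet_iterations=5)
        )
        assert ratch.length == plain.length

    def test_too_few_areas_rejected(self):
        m = random_matrix(3, 4, seed=0)
        with pytest.raises(ValueError):
            heuristic_search(m, SearchConfig(replicates=1, seed=0))


class TestCollapse:
    def test_collapse_is_idempotent(self):
        for seed in range(10):
            m = random_matrix(7, 5, seed=300 + seed)
            ls, nc = pack_matrix(m)
            adj = random_binary_tree(7, seed=seed)
            once = collapse_tree(adj, 7, ls, nc)
            twice = collapse_tree(once, 7, ls, nc)
            assert split_signature(once, 7) == split_signature(twice, 7)

    def test_uninformative_characters_collapse_to_star(self):
        # every character present in exactly one area: no internal support
        vals = np.eye(6, 5, k=-1, dtype=int)
        m = PresenceMatrix.from_arrays(
            [f"A{i}" for i in range(6)], [f"c{j}" for j in range(5)], vals, outgroup="A0"
        )
        ls, nc = pack_matrix(m)
        adj = random_binary_tree(6, seed=9)
        coll = collapse_tree(adj, 6, ls, nc)
        assert split_signature(coll, 6) == frozenset()

    def test_fully_supported_tree_unchanged(self):
        # characters mirror nested clades of a caterpillar: full support
        vals = np.array(
            [
                [0, 0, 0],
                [1, 0, 0],
                [1, 1, 0],
                [1, 1, 1],
                [1, 1, 1],
            ]
        )
        m = PresenceMatrix.from_arrays(
            ["A0", "A1", "A2", "A3", "A4"], ["x", "y", "z"], vals, outgroup="A0"
        )
        ts = branch_and_bound(m)
        assert ts.length == 3
        for t in ts.trees:
            ls, nc = pack_matrix(m)
            coll = collapse_tree(t.adj, 5, ls, nc)
            assert split_signature(coll, 5) == split_signature(t.adj, 5)


class TestStats:
    def test_homoplasy_free_matrix_has_ci_ri_one(self):
        vals = np.array(
            [
                [0, 0, 0],
                [1, 0, 0],
                [1, 1, 0],
                [1, 1, 1],
                [1, 1, 1],
            ]
        )
        m = PresenceMatrix.from_arrays(
            ["A0", "A1", "A2", "A3", "A4"], ["x", "y", "z"], vals, outgroup="A0"
        )
        ts = branch_and_bound(m)
        st = tree_stats(ts, m)
        assert st.s == st.m == 3
        assert st.ci == 1.0 and st.ri == 1.0

    def test_bounds_m_le_s_le_g(self):
        for seed in range(5):
            m = random_matrix(8, 10, seed=400 + seed)
            ts = heuristic_search(m, SearchConfig(replicates=3, seed=seed))
            st = tree_stats(ts, m)
            assert st.m <= st.s <= st.g
            assert 0 < st.ci <= 1
            assert 0 <= st.ri <= 1

    def test_display_rounding_is_half_up(self):
        assert display_round(23 / 38) == 0.605
        assert display_round(27 / 42) == 0.643
        assert display_round(0.0005) == 0.001
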