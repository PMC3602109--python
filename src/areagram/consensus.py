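"""Majority-rule consensus of area cladograms and character optimization.

The consensus contains exactly the ingroup clades occurring in strictly
more than ``cutoff`` of the input trees (default 50%), rooted on the
all-absent outgroup area.  Character states are then optimized onto the
(possibly polytomous) consensus with an exact two-pass dynamic program, so
gains and losses are classified over *all* most-parsimonious
reconstructions: a node is an unambiguous gain for a character only if
every optimal reconstruction places a 0->1 change on its subtending
branch; anything else is flagged ambiguous rather than resolved by
ACCTRAN/DELTRAN-style tie-breaking.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .matrix import PresenceMatrix
from .parsimony import TreeSet

__all__ = [
    "ConsensusNode",
    "ConsensusTree",
    "majority_consensus",
    "optimize_characters",
    "consensus_length",
]

INF = 10**9


@dataclass
class ConsensusNode:
    """A clade of the consensus: its leaf set, frequency among the input
    trees, children, and (after optimization) per-character changes."""

    leaves: frozenset[str]
    frequency: float
    children: list["ConsensusNode"] = field(default_factory=list)
    label: str | None = None  # leaf name for terminal nodes
    changes: list[tuple[str, str, bool]] = field(default_factory=list)
    # (character, "gain"/"loss", ambiguous_flag)

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class ConsensusTree:
    """Rooted majority-rule consensus over areas (outgroup = root sister)."""

    root: ConsensusNode
    outgroup: str
    cutoff: float
    n_trees: int

    def nodes(self) -> list[ConsensusNode]:
        out = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return out

    def internal_nodes(self) -> list[ConsensusNode]:
        return [nd for nd in self.nodes() if not nd.is_leaf]

    def clades(self) -> set[frozenset[str]]:
        return {nd.leaves for nd in self.internal_nodes()}

    @property
    def n_nodes(self) -> int:
        """Number of internal nodes (the root polytomy counts as one)."""
        return len(self.internal_nodes())

    def newick(self, with_frequencies: bool = True) -> str:
        def fmt(nd: ConsensusNode) -> str:
            if nd.is_leaf:
                return nd.label.replace(" ", "_")
            inner = ",".join(fmt(c) for c in nd.children)
            lab = ""
            if with_frequencies and nd.frequency:
                lab = f"{nd.frequency:.2f}"
            return f"({inner}){lab}"

        ingroup = fmt(self.root)
        return f"({self.outgroup.replace(' ', '_')},{ingroup});"

    def change_table(self) -> list[dict]:
        """Flat per-node character-change records (CSV-friendly)."""
        rows = []
        for nd in self.nodes():
            node_id = nd.label or "{" + ",".join(sorted(nd.leaves)) + "}"
            for char, kind, amb in nd.changes:
                rows.append(
                    {
                        "node": node_id,
                        "character": char,
                        "change": kind,
                        "ambiguous": amb,
                    }
                )
        return rows


def majority_consensus(trees: TreeSet, cutoff: float = 0.5) -> ConsensusTree:
    """Majority-rule consensus (strictly greater than ``cutoff``).

    All input trees must share one leaf set; they are rooted on the
    outgroup leaf of the first tree's label list before clades are
    counted.  With the default cutoff, a clade present in exactly half of
    the trees is dropped.
    """
    if not trees.trees:
        raise ValueError("empty tree set")
    first = trees.trees[0]
    labels = first.labels
    outgroup = labels[0]
    for t in trees.trees:
        if sorted(t.labels) != sorted(labels):
            raise ValueError("trees are on different leaf sets")

    counts: Counter[frozenset[str]] = Counter()
    for t in trees.trees:
        for clade in t.clades(outgroup):
            counts[clade] += 1
    n = len(trees.trees)
    ingroup = frozenset(l for l in labels if l != outgroup)
    keep = [c for c, k in counts.items() if k / n > cutoff and c != ingroup]
    keep.sort(key=lambda c: (len(c), sorted(c)))

    root = ConsensusNode(leaves=ingroup, frequency=1.0)
    nodes = [root]
    for clade in sorted(keep, key=len, reverse=True):
        nodes.append(ConsensusNode(leaves=clade, frequency=counts[clade] / n))
    # attach each node (and each leaf) under the smallest strict superset
    for nd in sorted(nodes[1:], key=lambda x: len(x.leaves), reverse=True):
        parent = min(
            (p for p in nodes if nd.leaves < p.leaves),
            key=lambda p: len(p.leaves),
        )
        parent.children.append(nd)
    for leaf in sorted(ingroup):
        parent = min(
            (p for p in nodes if leaf in p.leaves),
            key=lambda p: len(p.leaves),
        )
        parent.children.append(
            ConsensusNode(leaves=frozenset([leaf]), frequency=1.0, label=leaf)
        )
    return ConsensusTree(root=root, outgroup=outgroup, cutoff=cutoff, n_trees=n)


# ---------------------------------------------------------------------------
# exact binary-character optimization on a rooted (polytomous) tree
# ---------------------------------------------------------------------------

def _state_costs(tree: ConsensusTree, matrix: PresenceMatrix, char: str):
    """In/out DP tables for one binary character on the rooted consensus.

    The outgroup is handled as an extra child of the root carrying state 0.
    Returns (nodes, in_cost, out_cost, L) with in_cost[node][s] the minimum
    changes within the node's subtree given its state, out_cost[node][s]
    the minimum outside it, and L the tree-wide minimum.
    """
    col = matrix.data[char]

    order: list[ConsensusNode] = []

    def post(nd: ConsensusNode) -> None:
        for c in nd.children:
            post(c)
        order.append(nd)

    post(tree.root)
    in_cost: dict[int, list[int]] = {}
    for nd in order:
        if nd.is_leaf:
            s = int(col[nd.label])
            in_cost[id(nd)] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            costs = [0, 0]
            for s in (0, 1):
                tot = 0
                for c in nd.children:
                    ic = in_cost[id(c)]
                    tot += min(ic[s], ic[1 - s] + 1)
                costs[s] = tot
            in_cost[id(nd)] = costs
    # outgroup (state 0) joins at the root
    rc = in_cost[id(tree.root)]
    root_out = [0, 1]  # cost of the outgroup branch given the root state
    L = min(rc[0] + root_out[0], rc[1] + root_out[1])

    out_cost: dict[int, list[int]] = {id(tree.root): root_out}
    for nd in reversed(order):
        if nd.is_leaf:
            continue
        oc = out_cost[id(nd)]
        for child in nd.children:
            res = [INF, INF]
            for s_par in (0, 1):
                base = oc[s_par]
                for sib in nd.children:
                    if sib is child:
                        continue
                    ic = in_cost[id(sib)]
                    base += min(ic[s_par], ic[1 - s_par] + 1)
                for s in (0, 1):
                    tot = base + (1 if s != s_par else 0)
                    if tot < res[s]:
                        res[s] = tot
            out_cost[id(child)] = res
    return order, in_cost, out_cost, L


def optimize_characters(tree: ConsensusTree, matrix: PresenceMatrix) -> ConsensusTree:
    """Optimize every character onto the consensus, in place.

    For each non-root node and character, the joint cost of every
    (parent state, node state) combination is examined over all
    most-parsimonious reconstructions:

    * only (0, 1) optimal  -> unambiguous gain on the subtending branch;
    * only (1, 0) optimal  -> unambiguous loss;
    * a change co-optimal with no-change (or both directions) -> recorded
      with the ambiguous flag set.

    Returns the same tree for chaining.
    """
    leaf_names = {nd.label for nd in tree.nodes() if nd.is_leaf}
    missing = leaf_names.symmetric_difference(set(matrix.ingroup_areas))
    if missing:
        raise ValueError(f"consensus leaves != matrix areas: {sorted(missing)}")
    for nd in tree.nodes():
        nd.changes = []
    parent_of: dict[int, ConsensusNode] = {}
    for nd in tree.nodes():
        for c in nd.children:
            parent_of[id(c)] = nd
    for char in matrix.characters:
        order, in_cost, out_cost, L = _state_costs(tree, matrix, char)
        for nd in order:
            if nd is tree.root:
                continue
            par = parent_of[id(nd)]
            oc = out_cost[id(nd)]
            ic = in_cost[id(nd)]
            combo = {}
            for s_par in (0, 1):
                for s in (0, 1):
                    # oc already folds the parent-state choice; recompute
                    # jointly instead to pin both endpoint states.
                    combo[(s_par, s)] = _joint_cost(
                        tree, par, nd, s_par, s, in_cost, out_cost
                    )
            optimal = {k for k, v in combo.items() if v == L}
            gain = (0, 1) in optimal
            loss = (1, 0) in optimal
            same = (0, 0) in optimal or (1, 1) in optimal
            if gain and not loss and not same:
                nd.changes.append((char, "gain", False))
            elif loss and not gain and not same:
                nd.changes.append((char, "loss", False))
            elif gain or loss:
                kind = "gain" if gain else "loss"
                if gain and loss:
                    kind = "gain/loss"
                nd.changes.append((char, kind, True))
    return tree


def consensus_length(tree: ConsensusTree, matrix: PresenceMatrix) -> int:
    """Total parsimony changes of the matrix on the consensus topology
    (never less than the optimal binary-tree length: polytomies can only
    cost extra steps)."""
    total = 0
    for char in matrix.characters:
        _, _, _, L = _state_costs(tree, matrix, char)
        total += L
    return total


def _joint_cost(tree, par, nd, s_par, s, in_cost, out_cost) -> int:
    """Minimum total changes with the parent pinned to ``s_par`` and the
    node pinned to ``s``."""
    base = out_cost[id(par)][s_par]
    for sib in par.children:
        if sib is nd:
            continue
        ic = in_cost[id(sib)]
        base += min(ic[s_par], ic[1 - s_par] + 1)
    return base + in_cost[id(nd)][s] + (1 if s != s_par else 0)
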