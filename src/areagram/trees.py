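"""Light-weight unrooted tree machinery for the parsimony engine.

Trees over n leaves are stored as adjacency dicts ``{node: [neighbors]}``
with leaves numbered ``0..n-1`` (indices into an external list of area
labels) and internal nodes given arbitrary larger ids.  Topological
identity is tested through split sets: each internal edge contributes the
bitmask of the leaf side not containing leaf 0.

Newick import/export goes through dendropy.
"""
from __future__ import annotations

import dendropy

Adjacency = dict[int, list[int]]

__all__ = [
    "AreaTree",
    "splits",
    "split_signature",
    "rf_distance",
    "to_newick",
    "newick_to_adjacency",
]


def leaf_side_mask(adj: Adjacency, n_leaves: int, u: int, v: int) -> int:
    """Bitmask of leaves on the v-side of edge (u, v)."""
    mask = 0
    stack = [(u, v)]
    while stack:
        parent, node = stack.pop()
        if node < n_leaves:
            mask |= 1 << node
        for nb in adj[node]:
            if nb != parent:
                stack.append((node, nb))
    return mask


def splits(adj: Adjacency, n_leaves: int) -> frozenset[int]:
    """Nontrivial splits as leaf bitmasks, canonicalized to the side
    not containing leaf 0."""
    full = (1 << n_leaves) - 1
    out = set()
    seen = set()
    for u, vs in adj.items():
        for v in vs:
            if u > v or (u < n_leaves and v < n_leaves):
                continue
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            if u < n_leaves or v < n_leaves:
                continue  # trivial (leaf) edge
            m = leaf_side_mask(adj, n_leaves, u, v)
            if m & 1:
                m = full & ~m
            if m and m != full:
                out.add(m)
    return frozenset(out)


def split_signature(adj: Adjacency, n_leaves: int) -> frozenset[int]:
    return splits(adj, n_leaves)


def rf_distance(adj1: Adjacency, adj2: Adjacency, n_leaves: int) -> int:
    """Robinson-Foulds distance (symmetric difference of split sets)."""
    s1, s2 = splits(adj1, n_leaves), splits(adj2, n_leaves)
    return len(s1 ^ s2)


def _subtree_newick(adj: Adjacency, labels: list[str], parent: int, node: int) -> str:
    if node < len(labels):
        return labels[node].replace(" ", "_")
    parts = [_subtree_newick(adj, labels, node, nb) for nb in adj[node] if nb != parent]
    return "(" + ",".join(parts) + ")"


def to_newick(adj: Adjacency, labels: list[str], root_leaf: int | None = None) -> str:
    """Newick string, rooted on ``root_leaf`` (default: leaf 0)."""
    r = 0 if root_leaf is None else root_leaf
    hub = adj[r][0]
    inner = _subtree_newick(adj, labels, r, hub)
    return f"({labels[r].replace(' ', '_')},{inner});"


def newick_to_adjacency(newick: str, labels: list[str]) -> Adjacency:
    """Parse a Newick string onto the given leaf-label ordering.

    The tree is read as unrooted; a root of degree 2 is suppressed.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    index = {lab.replace(" ", "_"): i for i, lab in enumerate(labels)}
    adj: Adjacency = {}
    next_id = len(labels)
    node_id: dict = {}

    for node in tree.preorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_") if node.taxon else ""
            if name not in index:
                raise ValueError(f"leaf {name!r} not among expected labels")
            node_id[node] = index[name]
        else:
            node_id[node] = next_id
            next_id += 1
        adj.setdefault(node_id[node], [])
        if node.parent_node is not None:
            p = node_id[node.parent_node]
            adj[p].append(node_id[node])
            adj[node_id[node]].append(p)

    # suppress degree-2 nodes (e.g. the root of a rooted newick)
    for node in [u for u, vs in adj.items() if len(vs) == 2 and u >= len(labels)]:
        a, b = adj[node]
        adj[a] = [x if x != node else b for x in adj[a]]
        adj[b] = [x if x != node else a for x in adj[b]]
        del adj[node]
    return adj


class AreaTree:
    """An (unrooted) area cladogram: adjacency plus leaf labels.

    Displayed/rooted forms place the all-zero outgroup area as sister to
    the rest.
    """

    def __init__(self, adj: Adjacency, labels: list[str]):
        self.adj = adj
        self.labels = list(labels)
        self.n_leaves = len(labels)

    def splits(self) -> frozenset[int]:
        return splits(self.adj, self.n_leaves)

    def newick(self, root_label: str | None = None) -> str:
        root_leaf = None if root_label is None else self.labels.index(root_label)
        return to_newick(self.adj, self.labels, root_leaf)

    def clades(self, root_label: str) -> set[frozenset[str]]:
        """Rooted clades (leaf-label sets) when rooted on ``root_label``."""
        r = self.labels.index(root_label)
        full = (1 << self.n_leaves) - 1
        out: set[frozenset[str]] = set()
        for m in splits(self.adj, self.n_leaves):
            if m & (1 << r):
                m = full & ~m
            out.add(frozenset(self.labels[i] for i in range(self.n_leaves) if m >> i & 1))
        return out

    @classmethod
    def from_newick(cls, newick: str, labels: list[str]) -> "AreaTree":
        return cls(newick_to_adjacency(newick, labels), labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AreaTree):
            return NotImplemented
        return self.labels == other.labels and self.splits() == other.splits()

    def __hash__(self) -> int:
        return hash((tuple(self.labels), self.splits()))
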