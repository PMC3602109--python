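"""Parsimony engine for binary area x character matrices.

Characters are unordered, equally weighted, binary, with no missing data;
tree length is Fitch length.  State sets are packed into a pair of Python
integers per node (one bitmask per state, one bit per character), so a
Fitch merge is a handful of bitwise operations regardless of character
count.

The search machinery follows standard practice for small matrices:

* random-addition-sequence Wagner trees followed by TBR branch swapping,
  retaining every tree at the best length and swapping on all of them
  until closure ("swap to completion"), optionally accelerated by a
  parsimony ratchet;
* an exact branch-and-bound enumerator for small matrices, used as the
  internal exactness oracle;
* a branch collapse rule that deletes internal branches whose minimum
  length over all most-parsimonious reconstructions is zero, so counts of
  distinct optimal trees follow the usual convention.

TBR rearrangements are scored without rebuilding trees: bisecting an edge
leaves two subtrees whose lengths are rooting-invariant, and the length of
any reconnection is ``L1 + L2 + join``, where the join cost counts the
characters whose edge-view state sets in the two subtrees are disjoint.
"""
from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .matrix import PresenceMatrix
from .trees import Adjacency, AreaTree, split_signature

__all__ = [
    "SearchConfig",
    "TreeSet",
    "TreeStats",
    "fitch_length",
    "per_character_steps",
    "heuristic_search",
    "branch_and_bound",
    "exhaustive_search",
    "collapse_tree",
    "tree_stats",
    "display_round",
]


# ---------------------------------------------------------------------------
# character packing
# ---------------------------------------------------------------------------

def pack_matrix(matrix: PresenceMatrix) -> tuple[list[tuple[int, int]], int]:
    """Per-area Fitch leaf sets ``(mask_state0, mask_state1)``.

    Bit c of ``mask_state1`` is set iff character c is present in the area.
    Leaf order follows ``matrix.areas``.
    """
    vals = matrix.values()
    n_area, nchar = vals.shape
    full = (1 << nchar) - 1
    leafsets = []
    for i in range(n_area):
        m1 = 0
        row = vals[i]
        for c in range(nchar):
            if row[c]:
                m1 |= 1 << c
        leafsets.append((full & ~m1, m1))
    return leafsets, nchar


def _merge(a0: int, a1: int, b0: int, b1: int, full: int) -> tuple[int, int, int]:
    """Fitch merge of two state sets; returns (m0, m1, empty_mask)."""
    i0 = a0 & b0
    i1 = a1 & b1
    empty = full & ~(i0 | i1)
    if empty:
        i0 |= empty & (a0 | b0)
        i1 |= empty & (a1 | b1)
    return i0, i1, empty


# ---------------------------------------------------------------------------
# traversal helpers
# ---------------------------------------------------------------------------

def _reversed_preorder(adj: Adjacency, start: int, parent: int | None) -> list[tuple[int | None, int]]:
    """(parent, node) pairs with every node after all its descendants."""
    out = [(parent, start)]
    stack = [(parent, start)]
    while stack:
        p, u = stack.pop()
        for v in adj[u]:
            if v != p:
                out.append((u, v))
                stack.append((u, v))
    out.reverse()
    return out


def _dirsets(
    adj: Adjacency,
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    full: int,
    start: int,
    excl: int | None = None,
) -> tuple[dict[tuple[int, int], tuple[int, int, int]], int]:
    """Directional Fitch sets for the component containing ``start``.

    ``S[(a, b)] = (m0, m1, cost)``: the downpass state set and cost of the
    b-side subtree of edge (a, b).  Also returns the component's
    (rooting-invariant) Fitch length.
    """
    post = _reversed_preorder(adj, start, excl)
    S: dict[tuple[int, int], tuple[int, int, int]] = {}
    for p, u in post:
        if p is None:
            continue
        if u < n_leaves:
            m0, m1 = leafsets[u]
            S[(p, u)] = (m0, m1, 0)
        else:
            acc = None
            cost = 0
            for v in adj[u]:
                if v == p:
                    continue
                c0, c1, cc = S[(u, v)]
                cost += cc
                if acc is None:
                    acc = (c0, c1)
                else:
                    r0, r1, empty = _merge(acc[0], acc[1], c0, c1, full)
                    cost += empty.bit_count()
                    acc = (r0, r1)
            S[(p, u)] = (acc[0], acc[1], cost)
    # upward direction, preorder
    for p, u in reversed(post):
        nbrs = [v for v in adj[u] if v != excl]
        for v in nbrs:
            if v == p:
                continue
            acc = None
            cost = 0
            for w in nbrs:
                if w == v:
                    continue
                if w == p:
                    c0, c1, cc = S[(u, p)]
                else:
                    c0, c1, cc = S[(u, w)]
                cost += cc
                if acc is None:
                    acc = (c0, c1)
                else:
                    r0, r1, empty = _merge(acc[0], acc[1], c0, c1, full)
                    cost += empty.bit_count()
                    acc = (r0, r1)
            if acc is None:  # u is a leaf seen from v
                m0, m1 = leafsets[u]
                S[(v, u)] = (m0, m1, 0)
            else:
                S[(v, u)] = (acc[0], acc[1], cost)
    # component length from any edge
    length = 0
    for (a, b), (m0, m1, cost) in S.items():
        r0, r1, rc = S[(b, a)]
        i0, i1 = m0 & r0, m1 & r1
        join = (full & ~(i0 | i1)).bit_count()
        length = cost + rc + join
        break
    return S, length


def _pick_root(adj: Adjacency, n_leaves: int) -> int:
    """Internal node to root traversals on (every edge merge then counts)."""
    for u in adj:
        if u >= n_leaves or len(adj[u]) > 1:
            return u
    return next(iter(adj))


def _hartigan_down(children_sets: list[tuple[int, int]], nchar: int) -> tuple[int, int, list[int]]:
    """Hartigan downpass for a node with >2 children (exact on hard
    polytomies, where sequential Fitch folding is not).

    Returns (m0, m1, per_char_cost).  For each character, a state enters
    the downpass set iff it occurs in a maximum number of child sets, and
    the cost is (#children) - (that maximum).
    """
    d = len(children_sets)
    m0 = m1 = 0
    costs = [0] * nchar
    for c in range(nchar):
        bit = 1 << c
        c0 = sum(1 for s0, _ in children_sets if s0 & bit)
        c1 = sum(1 for _, s1 in children_sets if s1 & bit)
        k = max(c0, c1)
        if c0 == k:
            m0 |= bit
        if c1 == k:
            m1 |= bit
        costs[c] = d - k
    return m0, m1, costs


def fitch_length(
    adj: Adjacency,
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    nchar: int,
) -> int:
    """Exact parsimony length of an unrooted tree (Fitch on binary nodes,
    Hartigan on polytomies, which coincide at degree two)."""
    if len(adj) == 2:  # single edge between two leaves
        (a, b) = adj
        full = (1 << nchar) - 1
        _, _, empty = _merge(*leafsets[a], *leafsets[b], full)
        return empty.bit_count()
    full = (1 << nchar) - 1
    root = _pick_root(adj, n_leaves)
    post = _reversed_preorder(adj, root, None)
    S: dict[int, tuple[int, int]] = {}
    total = 0
    for p, u in post:
        if u < n_leaves:
            S[u] = leafsets[u]
            continue
        kids = [S[v] for v in adj[u] if v != p]
        if len(kids) == 1:
            S[u] = kids[0]
        elif len(kids) == 2:
            r0, r1, empty = _merge(kids[0][0], kids[0][1], kids[1][0], kids[1][1], full)
            total += empty.bit_count()
            S[u] = (r0, r1)
        else:
            m0, m1, costs = _hartigan_down(kids, nchar)
            total += sum(costs)
            S[u] = (m0, m1)
    return total


def per_character_steps(
    adj: Adjacency,
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    nchar: int,
) -> list[int]:
    """Parsimony step count per character."""
    steps = [0] * nchar
    if len(adj) == 2:
        (a, b) = adj
        full = (1 << nchar) - 1
        _, _, empty = _merge(*leafsets[a], *leafsets[b], full)
        while empty:
            low = empty & -empty
            steps[low.bit_length() - 1] += 1
            empty ^= low
        return steps
    full = (1 << nchar) - 1
    root = _pick_root(adj, n_leaves)
    post = _reversed_preorder(adj, root, None)
    S: dict[int, tuple[int, int]] = {}
    for p, u in post:
        if u < n_leaves:
            S[u] = leafsets[u]
            continue
        kids = [S[v] for v in adj[u] if v != p]
        if len(kids) == 1:
            S[u] = kids[0]
        elif len(kids) == 2:
            r0, r1, empty = _merge(kids[0][0], kids[0][1], kids[1][0], kids[1][1], full)
            while empty:
                low = empty & -empty
                steps[low.bit_length() - 1] += 1
                empty ^= low
            S[u] = (r0, r1)
        else:
            m0, m1, costs = _hartigan_down(kids, nchar)
            for c, cc in enumerate(costs):
                steps[c] += cc
            S[u] = (m0, m1)
    return steps


# ---------------------------------------------------------------------------
# tree surgery
# ---------------------------------------------------------------------------

def _relabel(adj: Adjacency, n_leaves: int) -> Adjacency:
    """Renumber internal nodes to n_leaves.. in a deterministic traversal."""
    mapping: dict[int, int] = {}
    nxt = n_leaves
    start = min(u for u in adj if u < n_leaves)
    order = _reversed_preorder(adj, start, None)
    for _, u in order:
        if u >= n_leaves and u not in mapping:
            mapping[u] = nxt
            nxt += 1
    out: Adjacency = {}
    for u, vs in adj.items():
        uu = mapping.get(u, u)
        out[uu] = [mapping.get(v, v) for v in vs]
    return out


def _remove_edge_component(
    adj: Adjacency, n_leaves: int, u: int, v: int
) -> tuple[Adjacency, int]:
    """Adjacency of the u-side component of edge (u, v), with the cut end
    suppressed if it drops to degree 2.  Returns (component, entry node)."""
    comp: Adjacency = {}
    stack = [(v, u)]
    while stack:
        p, x = stack.pop()
        comp[x] = [w for w in adj[x] if not (x == u and w == v)]
        for w in comp[x]:
            if w != p:
                stack.append((x, w))
    entry = u
    if len(comp[u]) == 2 and u >= n_leaves:
        a, b = comp[u]
        comp[a] = [x if x != u else b for x in comp[a]]
        comp[b] = [x if x != u else a for x in comp[b]]
        del comp[u]
        entry = a
    return comp, entry


def _component_edges(comp: Adjacency) -> list[tuple[int, int]]:
    out = []
    for a, vs in comp.items():
        for b in vs:
            if a < b:
                out.append((a, b))
    return out


def _reconnect(
    comp1: Adjacency,
    e1: tuple[int, int] | int,
    comp2: Adjacency,
    e2: tuple[int, int] | int,
    next_id: int,
) -> Adjacency:
    """Join two components at the given attachment points (edge to split,
    or bare node for a single-node component)."""
    adj: Adjacency = {}
    for comp in (comp1, comp2):
        for uu, vs in comp.items():
            adj[uu] = list(vs)
    ends = []
    for comp, e in ((comp1, e1), (comp2, e2)):
        if isinstance(e, tuple):
            x, y = e
            mid = next_id
            next_id += 1
            adj[x] = [w if w != y else mid for w in adj[x]]
            adj[y] = [w if w != x else mid for w in adj[y]]
            adj[mid] = [x, y]
            ends.append(mid)
        else:
            ends.append(e)
    a, b = ends
    adj[a] = adj.get(a, []) + [b]
    adj[b] = adj.get(b, []) + [a]
    return adj


# ---------------------------------------------------------------------------
# TBR scan
# ---------------------------------------------------------------------------

def _tbr_scan(
    adj: Adjacency,
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    nchar: int,
    threshold: int,
):
    """All TBR reconnection lengths for ``adj``.

    Returns ``(min_total, hits)`` where hits are ``(total, new_adjacency)``
    for every reconnection with total <= threshold (deduplication is the
    caller's business).
    """
    full = (1 << nchar) - 1
    min_total = None
    hits: list[tuple[int, Adjacency]] = []
    next_id = max(adj) + 1
    for u, v in _component_edges(adj):
        comp1, ent1 = _remove_edge_component(adj, n_leaves, u, v)
        comp2, ent2 = _remove_edge_component(adj, n_leaves, v, u)

        def attach_points(comp, entry):
            if len(comp) == 1:
                node = next(iter(comp))
                m0, m1 = leafsets[node]
                return [(node, m0, m1)], 0
            S, length = _dirsets(comp, n_leaves, leafsets, full, entry, None)
            pts = []
            for a, b in _component_edges(comp):
                s0, s1, _ = S[(a, b)]
                t0, t1, _ = S[(b, a)]
                m0, m1, _e = _merge(s0, s1, t0, t1, full)
                pts.append(((a, b), m0, m1))
            return pts, length

        pts1, L1 = attach_points(comp1, ent1)
        pts2, L2 = attach_points(comp2, ent2)
        base = L1 + L2
        for e1, a0, a1 in pts1:
            for e2, b0, b1 in pts2:
                join = (full & ~((a0 & b0) | (a1 & b1))).bit_count()
                total = base + join
                if min_total is None or total < min_total:
                    min_total = total
                if total <= threshold:
                    hits.append((total, _reconnect(comp1, e1, comp2, e2, next_id)))
    return min_total, hits


# ---------------------------------------------------------------------------
# collapse rule
# ---------------------------------------------------------------------------

def collapse_tree(
    adj: Adjacency,
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    nchar: int,
    rule: str = "min-length-zero",
) -> Adjacency:
    """Collapse internal branches of minimum length zero.

    A branch has minimum length zero iff, for every character, the Fitch
    state sets of its two edge directions intersect — i.e. some
    most-parsimonious reconstruction places no change on it.  Idempotent.
    """
    if rule == "none":
        return {u: list(vs) for u, vs in adj.items()}
    if rule != "min-length-zero":
        raise ValueError(f"unknown collapse rule {rule!r}")
    # Note: intersection of the two directional Fitch sets on an edge is
    # NOT an exact min-zero test (it can miss collapsible edges); the
    # per-character DP below is exact on any tree, polytomies included.
    zero_edges = _min_zero_edges_dp(adj, n_leaves, leafsets, nchar)
    return _contract(adj, n_leaves, zero_edges)


def _contract(adj: Adjacency, n_leaves: int, edges: list[tuple[int, int]]) -> Adjacency:
    parent: dict[int, int] = {u: u for u in adj}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    out: Adjacency = {}
    for u, vs in adj.items():
        ru = find(u)
        out.setdefault(ru, [])
        for v in vs:
            rv = find(v)
            if rv != ru:
                out[ru].append(rv)
    return _relabel(out, n_leaves)


def _min_zero_edges_dp(
    adj: Adjacency,
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    nchar: int,
) -> list[tuple[int, int]]:
    """Internal edges whose minimum length over all most-parsimonious
    reconstructions is zero, by exact per-character DP (valid on any
    tree, polytomies included)."""
    BIG = 10**6
    internal_edges = [
        (a, b) for a, b in _component_edges(adj) if a >= n_leaves and b >= n_leaves
    ]
    ok = {e: True for e in internal_edges}
    root = _pick_root(adj, n_leaves)
    order = _reversed_preorder(adj, root, None)
    for c in range(nchar):
        state = {i: (leafsets[i][1] >> c) & 1 for i in range(n_leaves)}
        g: dict[tuple[int, int], tuple[int, int]] = {}
        # downpass: g[(p,u)] = min cost of u-side given u's state
        for p, u in order:
            if p is None:
                continue
            if u < n_leaves:
                s = state[u]
                g[(p, u)] = (0 if s == 0 else BIG, 0 if s == 1 else BIG)
            else:
                c0 = c1 = 0
                for v in adj[u]:
                    if v == p:
                        continue
                    d0, d1 = g[(u, v)]
                    c0 += min(d0, d1 + 1)
                    c1 += min(d1, d0 + 1)
                g[(p, u)] = (c0, c1)
        # uppass
        for p, u in reversed(order):
            for v in adj[u]:
                if v == p:
                    continue
                c0 = c1 = 0
                for w in adj[u]:
                    if w == v:
                        continue
                    d0, d1 = g[(u, w)] if w != p else g[(u, p)]
                    c0 += min(d0, d1 + 1)
                    c1 += min(d1, d0 + 1)
                if u < n_leaves:
                    s = state[u]
                    g[(v, u)] = (0 if s == 0 else BIG, 0 if s == 1 else BIG)
                else:
                    g[(v, u)] = (c0, c1)
        for e in internal_edges:
            if not ok[e]:
                continue
            a, b = e
            a0, a1 = g[(b, a)]
            b0, b1 = g[(a, b)]
            same = min(a0 + b0, a1 + b1)
            diff = min(a0 + b1, a1 + b0) + 1
            if same > diff:  # every optimal reconstruction changes here
                ok[e] = False
    return [e for e, keep in ok.items() if keep]


# ---------------------------------------------------------------------------
# search configuration and results
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Heuristic-search settings (replicate counts follow common usage for
    matrices of this size: 100 random addition sequences, 10,000 trees
    retained)."""

    replicates: int = 100
    max_trees: int = 10000
    seed: int = 0
    ratchet: bool = False
    ratchet_iterations: int = 50
    collapse_rule: str = "min-length-zero"

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.max_trees < 1:
            raise ValueError("replicates and max_trees must be >= 1")


@dataclass
class TreeSet:
    """All equally parsimonious trees found, post-collapse and deduplicated."""

    trees: list[AreaTree]
    length: int
    per_character_steps: list[int]
    hit_max_trees: bool = False

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_newick(self, root_label: str | None = None) -> list[str]:
        return [t.newick(root_label) for t in self.trees]


@dataclass
class TreeStats:
    """Ensemble fit statistics of a tree set against its matrix.

    s: observed length; m: minimum conceivable length (one step per
    variable character); g: length on a completely unresolved tree
    (min(#1s, #0s) per binary character).  CI = m/s, RI = (g-s)/(g-m).
    """

    s: int
    m: int
    g: int
    ci_flag: str | None = None

    @property
    def ci(self) -> float:
        if self.s == 0:
            return 1.0
        return self.m / self.s

    @property
    def ri(self) -> float:
        if self.g == self.m:
            return 1.0
        return (self.g - self.s) / (self.g - self.m)

    @property
    def ci_display(self) -> float:
        return display_round(self.ci)

    @property
    def ri_display(self) -> float:
        return display_round(self.ri)


def display_round(x: float, places: int = 3) -> float:
    """Round half-up to ``places`` decimals, for display."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def tree_stats(best: TreeSet, matrix: PresenceMatrix) -> TreeStats:
    if not best.trees:
        raise ValueError("empty tree set")
    vals = matrix.values()
    n_area = vals.shape[0]
    ones = vals.sum(axis=0)
    m = int(((ones > 0) & (ones < n_area)).sum())
    g = int(np.minimum(ones, n_area - ones).sum())
    s = best.length
    flag = "zero-length; CI reported as 1.0" if s == 0 else None
    return TreeStats(s=s, m=m, g=g, ci_flag=flag)


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def _wagner_tree(
    n_leaves: int,
    leafsets: list[tuple[int, int]],
    nchar: int,
    rng: random.Random,
) -> Adjacency:
    """Stepwise-addition tree under a random addition sequence."""
    order = list(range(n_leaves))
    rng.shuffle(order)
    a, b, c = order[:3]
    hub = n_leaves
    adj: Adjacency = {hub: [a, b, c], a: [hub], b: [hub], c: [hub]}
    next_id = n_leaves + 1
    for leaf in order[3:]:
        best_len = None
        best_edges = []
        for u, v in _component_edges(adj):
            mid, tip_hub = next_id, next_id + 1
            adj[u] = [w if w != v else mid for w in adj[u]]
            adj[v] = [w if w != u else mid for w in adj[v]]
            adj[mid] = [u, v, leaf]
            adj[leaf] = [mid]
            L = fitch_length(adj, n_leaves, leafsets, nchar)
            # undo
            del adj[mid], adj[leaf]
            adj[u] = [w if w != mid else v for w in adj[u]]
            adj[v] = [w if w != mid else u for w in adj[v]]
            if best_len is None or L < best_len:
                best_len, best_edges = L, [(u, v)]
            elif L == best_len:
                best_edges.append((u, v))
        u, v = best_edges[rng.randrange(len(best_edges))]
        mid = next_id
        next_id += 1
        adj[u] = [w if w != v else mid for w in adj[u]]
        adj[v] = [w if w != u else mid for w in adj[v]]
        adj[mid] = [u, v, leaf]
        adj[leaf] = [mid]
    return _relabel(adj, n_leaves)


def _descend(adj, L, n_leaves, leafsets, nchar):
    """Steepest-descent TBR until no strictly better neighbor exists."""
    while True:
        min_total, hits = _tbr_scan(adj, n_leaves, leafsets, nchar, threshold=L - 1)
        if min_total is None or min_total >= L:
            return adj, L
        adj = _relabel(next(t for tot, t in hits if tot == min_total), n_leaves)
        L = min_total


def heuristic_search(matrix: PresenceMatrix, config: SearchConfig | None = None) -> TreeSet:
    """Random-addition Wagner trees + TBR, keeping all optimal trees.

    Every tree at the current best length is itself branch-swapped, and
    any equally parsimonious rearrangement with a new topology joins the
    pool, until the pool is closed under TBR (or ``max_trees`` is hit,
    which sets ``hit_max_trees`` on the result).  Distinctness is judged
    on topologies collapsed per ``config.collapse_rule``.
    """
    config = config or SearchConfig()
    labels = matrix.areas
    n_leaves = len(labels)
    if n_leaves < 4:
        raise ValueError("need at least 4 areas (including the outgroup)")
    leafsets, nchar = pack_matrix(matrix)
    rng = random.Random(config.seed)

    best: int | None = None
    pool: dict[frozenset, Adjacency] = {}  # collapsed signature -> binary representative
    queue: deque[frozenset] = deque()
    hit_cap = False

    def consider(adj: Adjacency, L: int) -> None:
        nonlocal best, pool, queue, hit_cap
        if best is None or L < best:
            best = L
            pool = {}
            queue.clear()
        if L == best:
            coll = collapse_tree(adj, n_leaves, leafsets, nchar, config.collapse_rule)
            sig = split_signature(coll, n_leaves)
            if sig not in pool:
                if len(pool) >= config.max_trees:
                    hit_cap = True
                    return
                pool[sig] = adj
                queue.append(sig)

    def drain() -> None:
        nonlocal best
        while queue:
            sig = queue.popleft()
            adj = pool.get(sig)
            if adj is None:
                continue
            min_total, hits = _tbr_scan(adj, n_leaves, leafsets, nchar, threshold=best)
            if min_total is not None and min_total < best:
                nb = next(t for tot, t in hits if tot == min_total)
                nb, L2 = _descend(_relabel(nb, n_leaves), min_total, n_leaves, leafsets, nchar)
                consider(nb, L2)
                continue
            for tot, t in hits:
                if tot == best:
                    consider(_relabel(t, n_leaves), tot)

    for _ in range(config.replicates):
        adj = _wagner_tree(n_leaves, leafsets, nchar, rng)
        L = fitch_length(adj, n_leaves, leafsets, nchar)
        adj, L = _descend(adj, L, n_leaves, leafsets, nchar)
        if best is not None and L > best:
            continue
        consider(adj, L)
        if config.ratchet:
            adj2 = adj
            for _i in range(config.ratchet_iterations):
                adj2, L2 = _ratchet_cycle(adj2, n_leaves, leafsets, nchar, rng)
                consider(adj2, L2)
        drain()

    trees = _collapsed_unique(pool, best, n_leaves, leafsets, nchar, config.collapse_rule, labels)
    steps = per_character_steps(trees[0].adj if trees else {}, n_leaves, leafsets, nchar)
    return TreeSet(trees=trees, length=best, per_character_steps=steps, hit_max_trees=hit_cap)


def _collapsed_unique(pool, best, n_leaves, leafsets, nchar, rule, labels) -> list[AreaTree]:
    seen: dict[frozenset, Adjacency] = {}
    for adj in pool.values():
        coll = collapse_tree(adj, n_leaves, leafsets, nchar, rule)
        sig = split_signature(coll, n_leaves)
        if sig not in seen:
            seen[sig] = coll
    ordered = sorted(seen.items(), key=lambda kv: sorted(kv[0]))
    return [AreaTree(adj, labels) for _, adj in ordered]


def _ratchet_cycle(adj, n_leaves, leafsets, nchar, rng):
    """One reweight-perturb-swap-restore cycle of the parsimony ratchet."""
    boosted = [c for c in range(nchar) if rng.random() < 0.25]
    dup = 0
    for c in boosted:
        dup |= 1 << c
    # double the weight of boosted characters by duplicating their bits
    ext_leafsets = []
    shift = nchar
    for m0, m1 in leafsets:
        e0, e1 = m0, m1
        for j, c in enumerate(boosted):
            if m0 >> c & 1:
                e0 |= 1 << (shift + j)
            if m1 >> c & 1:
                e1 |= 1 << (shift + j)
        ext_leafsets.append((e0, e1))
    ext_nchar = nchar + len(boosted)
    L = fitch_length(adj, n_leaves, ext_leafsets, ext_nchar)
    adj, _ = _descend(adj, L, n_leaves, ext_leafsets, ext_nchar)
    L = fitch_length(adj, n_leaves, leafsets, nchar)
    return _descend(adj, L, n_leaves, leafsets, nchar)


MAX_BB_AREAS = 14


def branch_and_bound(matrix: PresenceMatrix) -> TreeSet:
    """Provably complete search for all most-parsimonious trees.

    Practical for up to ~14 areas; refuses larger matrices.
    """
    labels = matrix.areas
    n_leaves = len(labels)
    if n_leaves > MAX_BB_AREAS:
        raise ValueError(
            f"branch-and-bound is limited to {MAX_BB_AREAS} areas; "
            f"got {n_leaves} (use heuristic_search)"
        )
    if n_leaves < 4:
        raise ValueError("need at least 4 areas")
    leafsets, nchar = pack_matrix(matrix)
    return _exact_search(matrix, labels, n_leaves, leafsets, nchar, prune=True)


def exhaustive_search(matrix: PresenceMatrix) -> TreeSet:
    """Evaluate every unrooted topology (tiny matrices; test oracle)."""
    labels = matrix.areas
    n_leaves = len(labels)
    if n_leaves > 9:
        raise ValueError("exhaustive enumeration limited to 9 areas")
    leafsets, nchar = pack_matrix(matrix)
    return _exact_search(matrix, labels, n_leaves, leafsets, nchar, prune=False)


def _exact_search(matrix, labels, n_leaves, leafsets, nchar, prune: bool) -> TreeSet:
    best: list[int | None] = [None]
    optima: list[Adjacency] = []

    hub = n_leaves
    adj: Adjacency = {hub: [0, 1, 2], 0: [hub], 1: [hub], 2: [hub]}

    def recurse(adj: Adjacency, k: int, next_id: int) -> None:
        L = fitch_length(adj, n_leaves, leafsets, nchar)
        if prune and best[0] is not None and L > best[0]:
            return
        if k == n_leaves:
            if best[0] is None or L < best[0]:
                best[0] = L
                optima.clear()
            if L == best[0]:
                optima.append(_relabel({u: list(vs) for u, vs in adj.items()}, n_leaves))
            return
        for u, v in _component_edges(adj):
            mid = next_id
            adj[u] = [w if w != v else mid for w in adj[u]]
            adj[v] = [w if w != u else mid for w in adj[v]]
            adj[mid] = [u, v, k]
            adj[k] = [mid]
            recurse(adj, k + 1, next_id + 1)
            del adj[mid], adj[k]
            adj[u] = [w if w != mid else v for w in adj[u]]
            adj[v] = [w if w != mid else u for w in adj[v]]

    recurse(adj, 3, n_leaves + 1)
    pool = {split_signature(a, n_leaves): a for a in optima}
    trees = _collapsed_unique(pool, best[0], n_leaves, leafsets, nchar, "min-length-zero", labels)
    steps = per_character_steps(optima[0], n_leaves, leafsets, nchar)
    return TreeSet(trees=trees, length=best[0], per_character_steps=steps)


def tree_length(matrix: PresenceMatrix, tree: AreaTree) -> tuple[int, list[int]]:
    """Fitch length and per-character steps of a given tree on a matrix."""
    if sorted(tree.labels) != sorted(matrix.areas):
        raise ValueError("tree leaves do not match matrix areas")
    if tree.labels != matrix.areas:
        # re-index leaf sets to the tree's label order
        order = [matrix.areas.index(lab) for lab in tree.labels]
        leafsets_all, nchar = pack_matrix(matrix)
        leafsets = [leafsets_all[i] for i in order]
    else:
        leafsets, nchar = pack_matrix(matrix)
    n_leaves = len(tree.labels)
    total = fitch_length(tree.adj, n_leaves, leafsets, nchar)
    steps = per_character_steps(tree.adj, n_leaves, leafsets, nchar)
    return total, steps
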