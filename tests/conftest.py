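import itertools
import random

import numpy as np
import pytest

from areagram import PresenceMatrix, SearchConfig, datasets, heuristic_search
from areagram.parsimony import _component_edges, _relabel


def random_matrix(n_areas: int, n_chars: int, seed: int) -> PresenceMatrix:
    """Random binary matrix with an all-zero outgroup in row 0."""
    r = np.random.RandomState(seed)
    vals = r.randint(0, 2, size=(n_areas, n_chars))
    vals[0] = 0
    return PresenceMatrix.from_arrays(
        [f"A{i}" for i in range(n_areas)],
        [f"c{j}" for j in range(n_chars)],
        vals,
        outgroup="A0",
    )


def random_binary_tree(n_leaves: int, seed: int, polytomy_prob: float = 0.0) -> dict:
    """Random unrooted tree adjacency over leaves 0..n-1."""
    rng = random.Random(seed)
    hub = n_leaves
    adj = {hub: [0, 1, 2], 0: [hub], 1: [hub], 2: [hub]}
    nxt = n_leaves + 1
    for k in range(3, n_leaves):
        if polytomy_prob and rng.random() < polytomy_prob:
            node = rng.choice([u for u in adj if u >= n_leaves])
            adj[node].append(k)
            adj[k] = [node]
            continue
        u, v = rng.choice(_component_edges(adj))
        mid = nxt
        nxt += 1
        adj[u] = [w if w != v else mid for w in adj[u]]
        adj[v] = [w if w != u else mid for w in adj[v]]
        adj[mid] = [u, v, k]
        adj[k] = [mid]
    return _relabel(adj, n_leaves)


def brute_force_length(adj: dict, n_leaves: int, vals: np.ndarray) -> int:
    """Independent parsimony oracle: enumerate every assignment of states
    to internal nodes, character by character."""
    internal = [u for u in adj if u >= n_leaves]
    edges = [(a, b) for a in adj for b in adj[a] if a < b]
    total = 0
    for c in range(vals.shape[1]):
        best = None
        for assign in itertools.product((0, 1), repeat=len(internal)):
            st = dict(zip(internal, assign))
            for i in range(n_leaves):
                st[i] = int(vals[i, c])
            L = sum(1 for a, b in edges if st[a] != st[b])
            best = L if best is None else min(best, L)
        total += best
    return total


def random_taxon_newick(labels: list[str], seed: int) -> str:
    """Random rooted binary tree over the given labels, internal nodes
    labelled anc1..anc(k)."""
    rng = random.Random(seed)
    units = [lab for lab in labels]
    rng.shuffle(units)
    counter = 0
    while len(units) > 1:
        i, j = sorted(rng.sample(range(len(units)), 2))
        counter += 1
        merged = f"({units[i]},{units[j]})anc{counter}"
        units = [u for k, u in enumerate(units) if k not in (i, j)] + [merged]
    return units[0] + ";"


# expensive fixture searches shared across tests (the TBR closure makes the
# result independent of replicate count / seed at this matrix size)
@pytest.fixture(scope="session")
def pae_trees():
    return heuristic_search(
        datasets.load_province_matrix(), SearchConfig(replicates=20, seed=1)
    )


@pytest.fixture(scope="session")
def bpa_trees():
    return heuristic_search(
        datasets.load_bpa_matrix(), SearchConfig(replicates=20, seed=1)
    )
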