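"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import alupop as ap
from alupop.haplotype_em import enumerate_compatible_pairs


@pytest.fixture(scope="session")
def drb1_freqs():
    return ap.load_reference_table("T2")


@pytest.fixture(scope="session")
def alu_freqs():
    return ap.load_reference_table("T3")[0]


@pytest.fixture(scope="session")
def alu_counts():
    return ap.load_reference_table("T3")[1]


@pytest.fixture(scope="session")
def hap_fixture():
    return ap.load_reference_table("T4")


def biallelic_counts(n11: int, n12: int, n22: int, name: str = "L",
                     population: str = "pop") -> ap.GenotypeCounts:
    counts = {}
    if n11:
        counts[("1", "1")] = n11
    if n12:
        counts[("1", "2")] = n12
    if n22:
        counts[("2", "2")] = n22
    return ap.GenotypeCounts(ap.alu_locus(name), population,
                             n11 + n12 + n22, counts)


# ---------------------------------------------------------------------------
# Independent likelihood oracle for EM: simplex grid search
# ---------------------------------------------------------------------------

def pattern_log_likelihood(patterns: dict, hap_order: list, f: np.ndarray) -> float:
    """Multinomial log-likelihood of haplotype frequencies given unphased
    genotype patterns; computed directly from the compatible-pair sums,
    independently of the EM implementation."""
    index = {h: i for i, h in enumerate(hap_order)}
    ll = 0.0
    for g, mult in patterns.items():
        tot = 0.0
        for h1, h2 in enumerate_compatible_pairs(g):
            coef = 2.0 if h1 != h2 else 1.0
            tot += coef * f[index[h1]] * f[index[h2]]
        if tot <= 0:
            return -math.inf
        ll += mult * math.log(tot)
    return ll


def grid_search_max_loglik(patterns: dict, step: float = 0.001):
    """Maximize the likelihood over the haplotype-frequency simplex by grid
    search: a coarse full grid (step 0.05) followed by greedy mass-transfer
    refinement on successively finer lattices down to ``step``.

    Only intended for small haplotype spaces (<= 4 distinct haplotypes).
    """
    hap_order = sorted({h for g in patterns
                        for pair in enumerate_compatible_pairs(g) for h in pair})
    k = len(hap_order)
    assert k <= 4, "grid oracle limited to <= 4 haplotypes"
    coarse = 20  # 1/0.05
    best_f, best_ll = None, -math.inf
    for comp in itertools.product(range(coarse + 1), repeat=k - 1):
        if sum(comp) > coarse:
            continue
        f = np.array(list(comp) + [coarse - sum(comp)], dtype=float) / coarse
        ll = pattern_log_likelihood(patterns, hap_order, f)
        if ll > best_ll:
            best_ll, best_f = ll, f
    schedule = []
    lattice = 0.05
    while lattice > step:
        lattice = max(lattice / 5.0, step)
        schedule.append(lattice)
    for lattice in schedule:
        improved = True
        while improved:
            improved = False
            for i in range(k):
                for j in range(k):
                    if i == j or best_f[i] < lattice - 1e-12:
                        continue
                    f = best_f.copy()
                    f[i] -= lattice
                    f[j] += lattice
                    ll = pattern_log_likelihood(patterns, hap_order, f)
                    if ll > best_ll + 1e-13:
                        best_ll, best_f = ll, f
                        improved = True
    return hap_order, best_f, best_ll


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree with branch lengths in [0.1, 1] and its
    additive leaf-to-leaf distance matrix (path lengths on the tree)."""
    # adjacency: node -> {neighbor: length}; leaves are "L0".."L{n-1}"
    adj: dict[str, dict[str, float]] = {}
    nxt = [0]

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.1, 1.0))

    add_edge("L0", "I0", blen())
    add_edge("L1", "I0", blen())
    add_edge("L2", "I0", blen())
    n_internal = 1
    for leaf in range(3, n_leaves):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = f"I{n_internal}"
        n_internal += 1
        del adj[a][b], adj[b][a]
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * split)
        add_edge(b, mid, w * (1 - split))
        add_edge(f"L{leaf}", mid, blen())
    labels = [f"L{i}" for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        # Dijkstra is overkill on a tree: BFS accumulating path length
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    sides = set()
    all_leaves = frozenset(labels)
    for a in adj:
        for b in adj[a]:
            if a < b:
                # leaves on a's side when edge (a,b) is cut
                seen = {a}
                stack = [a]
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if (u, v) == (a, b) or v in seen:
                            continue
                        seen.add(v)
                        stack.append(v)
                side = frozenset(x for x in seen if x.startswith("L"))
                if 1 < len(side) < n_leaves - 1:
                    sides.add(side)
                    sides.add(all_leaves - side)
    return labels, d, sides
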