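"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, closed forms, NNLS
fits) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.optimize import nnls


# ---------------------------------------------------------------------------
# Tree topology enumeration + least-squares branch lengths

def enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Edges are (node, node) tuples; leaves are 0..n-1, internal nodes are
    numbered from n upward. Built by attaching each new leaf to every edge
    of every smaller topology (1, 3, 15, 105 ... topologies).
    """
    assert n_leaves >= 3
    base = [[(0, n_leaves), (1, n_leaves), (2, n_leaves)]]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        grown = []
        for edges in base:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1 :]
                mid = next_internal
                grown.append(new + [(u, mid), (v, mid), (leaf, mid)])
        base = grown
        next_internal += 1
    return base


def _paths(edges, n_leaves):
    """Leaf-pair -> set of edge indices, via adjacency walks."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a, b in itertools.combinations(range(n_leaves), 2):
        # DFS from a to b
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, path = stack.pop()
            if node == b:
                out[(a, b)] = path
                break
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, path + [eidx]))
    return out


def least_squares_tree(d: np.ndarray):
    """Best-fitting topology/branch lengths over ALL topologies (n <= 6).

    Returns (bipartitions, sse, leaf_edge_lengths) of the minimum
    sum-of-squares topology under non-negative branch lengths.
    """
    n = d.shape[0]
    best = None
    for edges in enumerate_topologies(n):
        paths = _paths(edges, n)
        pairs = list(itertools.combinations(range(n), 2))
        A = np.zeros((len(pairs), len(edges)))
        y = np.array([d[a, b] for a, b in pairs])
        for row, pair in enumerate(pairs):
            for eidx in paths[pair]:
                A[row, eidx] = 1.0
        x, rnorm = nnls(A, y)
        sse = rnorm**2
        if best is None or sse < best[1] - 1e-12:
            best = (edges, sse, x)
    edges, sse, x = best
    bips = topology_bipartitions(edges, n)
    leaf_lengths = {}
    for idx, (u, v) in enumerate(edges):
        leaf = u if u < n else (v if v < n else None)
        if leaf is not None:
            leaf_lengths[leaf] = x[idx]
    return bips, sse, leaf_lengths


def topology_bipartitions(edges, n_leaves):
    """Nontrivial splits of an edge-list topology, canonicalized away from leaf 0."""
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) is removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            out.add(frozenset(side))
    return out


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random topology with lengths in [0.1, 2]; returns (edges, lengths, D)."""
    topologies = enumerate_topologies(n_leaves)
    edges = topologies[int(rng.integers(len(topologies)))]
    lengths = rng.uniform(0.1, 2.0, size=len(edges))
    paths = _paths(edges, n_leaves)
    d = np.zeros((n_leaves, n_leaves))
    for (a, b), eidxs in paths.items():
        d[a, b] = d[b, a] = sum(lengths[e] for e in eidxs)
    return edges, lengths, d


# ---------------------------------------------------------------------------
# Hypergeometric enrichment by enumeration

def enrichment_p_bruteforce(N: int, region: set[int], n_pred: int, x_obs: int) -> float:
    """P(overlap >= x_obs) over ALL size-n subsets of positions 1..N."""
    hits = 0
    total = comb(N, n_pred)
    for subset in itertools.combinations(range(1, N + 1), n_pred):
        if len(region.intersection(subset)) >= x_obs:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Type-II permutation p by enumeration on one column

def type2_exact_p_column(column: str, n_a: int) -> float:
    """Exact permutation p for one gap-free column split into n_a | rest.

    Re-implements the T statistic from its definition: modal-residue
    frequencies in each group, alphabetical tie-break, times an indicator
    that the modal residues differ.
    """

    def t_of(groups):
        freqs = []
        cons = []
        for g in groups:
            counts: dict[str, int] = {}
            for ch in g:
                counts[ch] = counts.get(ch, 0) + 1
            best = min(counts, key=lambda r: (-counts[r], r))
            cons.append(best)
            freqs.append(counts[best] / len(g))
        return freqs[0] * freqs[1] * (cons[0] != cons[1])

    chars = list(column)
    idx = range(len(chars))
    t_obs = t_of([chars[:n_a], chars[n_a:]])
    hits = total = 0
    for combo in itertools.combinations(idx, n_a):
        combo_set = set(combo)
        ga = [chars[i] for i in combo]
        gb = [chars[i] for i in idx if i not in combo_set]
        total += 1
        if t_of([ga, gb]) >= t_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Tryptic digestion by pattern scan

def digest_fragments_oracle(sequence: str) -> list[tuple[int, int]]:
    """Fully cleaved tryptic fragments as 1-based inclusive ranges."""
    import re

    cuts = [m.start() for m in re.finditer("(?<=[KR])(?!P)", sequence)
            if 0 < m.start() < len(sequence)]
    bounds = [0] + cuts + [len(sequence)]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]
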