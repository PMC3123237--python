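"""Independent, naively coded reference implementations used as oracles.

Everything here is deliberately written from scratch, the slow way: explicit
edge-list scans, no incremental bookkeeping, no shared code with the package
under test.  The reference interpreter follows the same documented
conventions as the package (FIFO queue ordered by descending weight with
lexicographic tie-break, per-seed visited set, skip-on-pop, cull to a fixed
point then trim, first-hit merging) — the independence is in the
implementation, not the contract.
"""

from __future__ import annotations

import itertools
import math
from math import comb


def edges_of(graph) -> list[tuple[str, str]]:
    return [tuple(sorted(e)) for e in graph.edges()]


# ---------------------------------------------------------------- weighting

def brute_vertex_weight(graph, v):
    """(k_max, density, weight) by explicit induced-subgraph construction."""
    hood = sorted(set(graph.adj[v]) | {v})
    n = len(hood)
    induced = [
        (a, b) for a, b in itertools.combinations(hood, 2) if graph.has_edge(a, b)
    ]
    density = 0.0 if n <= 1 else 2 * len(induced) / (n * (n - 1))
    k_max = max(graph.degree(u) for u in hood)
    return k_max, density, k_max * density


# -------------------------------------------------------------- modularity

def brute_local_modularity(graph, members):
    members = set(members)
    e_in = sum(1 for a, b in edges_of(graph) if a in members and b in members)
    e_out = sum(1 for a, b in edges_of(graph) if (a in members) != (b in members))
    if e_in == 0:
        return 0.0
    if e_out == 0:
        return math.inf
    return e_in / e_out


def brute_density(graph, members):
    members = set(members)
    k = len(members)
    if k <= 1:
        return 0.0
    e_in = sum(1 for a, b in edges_of(graph) if a in members and b in members)
    return 2 * e_in / (k * (k - 1))


# ------------------------------------------------------------ hypergeometric

def enumerate_overlap_pvalue(population, complex_size, cluster_size, overlap):
    """P(X >= overlap) by exhaustive enumeration of all draws (small inputs)."""
    annotated = set(range(complex_size))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(population), cluster_size):
        total += 1
        if len(annotated.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


def closed_form_overlap_pvalue(population, complex_size, cluster_size, overlap):
    """Same tail by the closed-form sum of hypergeometric terms."""
    num = sum(
        comb(complex_size, k) * comb(population - complex_size, cluster_size - k)
        for k in range(overlap, min(complex_size, cluster_size) + 1)
    )
    return num / comb(population, cluster_size)


# -------------------------------------------------- step-by-step interpreter

def _mod(e_in, e_out):
    if e_in == 0:
        return 0.0
    if e_out == 0:
        return math.inf
    return e_in / e_out


def _mod_of(graph, members):
    return brute_local_modularity(graph, members)


def _passes_a(new, old, msp):
    if math.isinf(old):
        return math.isinf(new) and msp > 0
    return new > old - old * msp


def _passes_b(new, old, msp):
    if math.isinf(old):
        return False
    return new > old + old * msp


def reference_weights(graph):
    return {v: brute_vertex_weight(graph, v)[2] for v in graph.nodes()}


def reference_grow(graph, weights, seed, vwp, msp, trim):
    def order(nodes):
        return sorted(nodes, key=lambda u: (-weights[u], u))

    members = {seed}
    visited = {seed}
    queue = [(n, seed) for n in order(graph.adj[seed])]
    while queue:
        n, source = queue.pop(0)
        if n in members or n in visited:
            continue
        visited.add(n)
        old = _mod_of(graph, members)
        new = _mod_of(graph, members | {n})
        weight_ok = weights[n] >= weights[source] * (1 - vwp)
        if (weight_ok and _passes_a(new, old, msp)) or _passes_b(new, old, msp):
            members.add(n)
            for nb in order(graph.adj[n]):
                if nb not in members and nb not in visited:
                    queue.append((nb, n))
    # cull to fixed point, lexicographic scan, restart after each removal
    while True:
        removed = False
        for v in sorted(members):
            if _passes_b(
                _mod_of(graph, members - {v}), _mod_of(graph, members), msp
            ):
                members = members - {v}
                removed = True
                break
        if not removed:
            break
    if trim:
        degree_in = {
            v: sum(1 for u in graph.adj[v] if u in members) for v in members
        }
        members = {v for v in members if degree_in[v] >= 2}
    return members


def reference_mine(graph, vwp, msp, mp, trim, min_size):
    """Full pipeline; returns the ranked list of member frozensets."""
    weights = reference_weights(graph)
    seeds = sorted(graph.nodes(), key=lambda v: (-weights[v], v))
    clusters: list[frozenset] = []
    for seed in seeds:
        candidate = frozenset(reference_grow(graph, weights, seed, vwp, msp, trim))
        merged = False
        for i, existing in enumerate(clusters):
            smaller = min(len(existing), len(candidate))
            overlap = len(existing & candidate) / smaller if smaller else 0.0
            if overlap >= mp:
                clusters[i] = existing | candidate
                merged = True
                break
        if not merged:
            clusters.append(candidate)
    kept = [c for c in clusters if len(c) >= min_size]

    def score(members):
        return brute_density(graph, members) * len(members)

    kept.sort(key=lambda c: (-score(c), -len(c), min(c)))
    return kept
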