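"""Seeded benchmark-graph generators with known ground-truth modules.

Real interactomes span two topological regimes: sparse, strongly modular
networks (high characteristic path length, clearly separated complexes) and
dense, highly interconnected ones (short paths, blurred module boundaries).
Two generators cover that span with exact, seeded reproducibility:

* :func:`ring_of_cliques` — disjoint complete cliques arranged in a ring,
  consecutive cliques joined by a single bridge edge, plus optional uniform
  noise edges.  Each clique has exactly two boundary edges, so its local
  modularity is ``E_in / 2`` in closed form — the sparse/modular regime and
  the canonical planted-recovery fixture.
* :func:`planted_partition` — blocks of equal size with independent edge
  probability ``p_in`` inside blocks and ``p_out`` between them.  Sliding
  ``p_out`` toward ``p_in`` moves the graph from the modular regime to the
  dense interconnected one.

Randomness comes from :class:`numpy.random.Generator` seeded with PCG64;
the same spec and seed always produce bit-identical edge sets.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .graph_io import AnnotationSet

__all__ = ["ring_of_cliques", "planted_partition"]


def _node_name(prefix: str, block: int, index: int) -> str:
    # zero-padded so lexicographic order matches construction order
    return f"{prefix}{block:03d}n{index:03d}"


def ring_of_cliques(
    n_cliques: int,
    clique_size: int,
    n_noise_edges: int = 0,
    seed: int = 0,
) -> tuple[nx.Graph, AnnotationSet]:
    """A ring of complete cliques with single bridge edges and optional noise.

    Clique ``i`` is a complete graph on ``clique_size`` nodes; its last
    member is bridged to the first member of clique ``i+1`` (ring-closing at
    the end), so every clique has exactly two boundary edges.
    ``n_noise_edges`` additional distinct edges are drawn uniformly from the
    remaining non-adjacent pairs with the seeded RNG.

    Returns the graph and the cliques as ground-truth annotation sets.
    """
    if n_cliques < 2:
        raise ValueError("n_cliques must be >= 2")
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    if n_noise_edges < 0:
        raise ValueError("n_noise_edges must be >= 0")

    graph = nx.Graph()
    truth = AnnotationSet(name="ring_of_cliques")
    cliques: list[list[str]] = []
    for i in range(n_cliques):
        members = [_node_name("c", i, j) for j in range(clique_size)]
        cliques.append(members)
        for a_idx in range(clique_size):
            for b_idx in range(a_idx + 1, clique_size):
                graph.add_edge(members[a_idx], members[b_idx])
        truth.sets[f"clique_{i:03d}"] = frozenset(members)
        truth.descriptions[f"clique_{i:03d}"] = f"planted clique {i}"
    for i in range(n_cliques):
        graph.add_edge(cliques[i][-1], cliques[(i + 1) % n_cliques][0])

    if n_noise_edges:
        nodes = sorted(graph.nodes())
        candidates = [
            (a, b)
            for ai, a in enumerate(nodes)
            for b in nodes[ai + 1 :]
            if not graph.has_edge(a, b)
        ]
        if n_noise_edges > len(candidates):
            raise ValueError(
                f"cannot place {n_noise_edges} noise edges; only "
                f"{len(candidates)} non-adjacent pairs available"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(candidates), size=n_noise_edges, replace=False)
        for idx in sorted(int(i) for i in chosen):
            graph.add_edge(*candidates[idx])
    return graph, truth


def planted_partition(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[nx.Graph, AnnotationSet]:
    """A planted-partition random graph with blocks as ground truth.

    Every within-block pair is an edge with probability ``p_in``, every
    between-block pair with probability ``p_out`` (requires
    ``0 <= p_out <= p_in <= 1``); all draws come from one seeded PCG64
    stream, iterating node pairs in a fixed order, so generation is a pure
    function of the spec.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be >= 1")
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}")

    rng = np.random.default_rng(seed)
    nodes = [
        _node_name("b", i, j) for i in range(n_blocks) for j in range(block_size)
    ]
    block_of = np.repeat(np.arange(n_blocks), block_size)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    truth = AnnotationSet(name="planted_partition")
    for i in range(n_blocks):
        members = nodes[i * block_size : (i + 1) * block_size]
        truth.sets[f"block_{i:03d}"] = frozenset(members)
        truth.descriptions[f"block_{i:03d}"] = f"planted block {i}"

    n = len(nodes)
    for i in range(n - 1):
        probs = np.where(block_of[i + 1 :] == block_of[i], p_in, p_out)
        draws = rng.random(n - i - 1)
        for offset in np.nonzero(draws < probs)[0]:
            graph.add_edge(nodes[i], nodes[i + 1 + int(offset)])
    return graph, truth
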