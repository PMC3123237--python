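"""Vertex weighting: the seed-ordering score of the clustering algorithm.

Every vertex *v* is scored on its inclusive depth-1 neighbourhood
``N ∪ v`` (v plus its direct neighbours):

* ``density d = 2 e / (n (n - 1))`` where *n* is the neighbourhood size and
  *e* the number of graph edges with both endpoints inside the neighbourhood,
* ``k_max`` — the largest whole-graph degree of any vertex in the
  neighbourhood (including *v* itself),
* ``weight v_w = k_max * d``.

The product boosts densely grouped vertices attached to hubs, which tend to
sit inside functional modules, so they are inspected first when clusters are
seeded.  Degenerate neighbourhoods of size <= 1 (isolated vertices) take
density 0 and hence weight 0: they can never seed or join a cluster on
weight grounds.

``k_max`` deliberately uses degrees measured in the full graph, not within
the induced neighbourhood subgraph: the maximal number of edges connected to
any single neighbourhood member is its total edge count.

Weights are computed once per graph and never updated during clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["VertexWeights", "neighborhood_density", "compute_vertex_weights"]


@dataclass
class VertexWeights:
    """Per-vertex weight table: degree, k_max, neighbourhood density, weight."""

    degree: dict[str, int] = field(default_factory=dict)
    k_max: dict[str, int] = field(default_factory=dict)
    density: dict[str, float] = field(default_factory=dict)
    weight: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per node), sorted by node identifier."""
        nodes = sorted(self.weight)
        return pd.DataFrame(
            {
                "node": nodes,
                "degree": [self.degree[n] for n in nodes],
                "k_max": [self.k_max[n] for n in nodes],
                "density": [self.density[n] for n in nodes],
                "weight": [self.weight[n] for n in nodes],
            }
        )


def neighborhood_density(graph: nx.Graph, v: str) -> float:
    """Density of the inclusive neighbourhood of ``v``: 2e/(n(n-1)), 0 if n <= 1."""
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    hood = set(graph.adj[v]) | {v}
    n = len(hood)
    if n <= 1:
        return 0.0
    e = sum(1 for u in hood for w in graph.adj[u] if w in hood) // 2
    return 2.0 * e / (n * (n - 1))


def compute_vertex_weights(graph: nx.Graph) -> VertexWeights:
    """Compute degree, k_max, density and weight for every node of ``graph``."""
    degrees = dict(graph.degree())
    adj = {v: set(graph.adj[v]) for v in graph.nodes()}
    table = VertexWeights()
    for v in graph.nodes():
        hood = adj[v] | {v}
        n = len(hood)
        if n <= 1:
            density = 0.0
            e = 0
        else:
            e = sum(len(adj[u] & hood) for u in hood) // 2
            density = 2.0 * e / (n * (n - 1))
        k_max = max(degrees[u] for u in hood)
        table.degree[v] = degrees[v]
        table.k_max[v] = k_max
        table.density[v] = density
        table.weight[v] = k_max * density
    return table
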