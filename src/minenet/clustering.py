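"""The clustering core: seed-expansion growth, culling, trimming, merging.

The algorithm is agglomerative and non-exclusive.  Every node is inspected
as a seed in order of descending vertex weight; from each seed a cluster is
grown breadth-first, admitting a candidate neighbour *n* (enqueued by a
member ``v_s``) iff either

A) ``weight(n) >= weight(v_s) * (1 - vwp)`` and admitting *n* does not
   decrease the cluster's local modularity by a relative margin of ``msp``
   (``mod(C ∪ n) > mod(C) - mod(C) * msp``), or
B) admitting *n* improves local modularity by more than the same relative
   margin (``mod(C ∪ n) > mod(C) + mod(C) * msp``) even if the weight test
   fails.

Local modularity of a member set is ``E_in / E_out`` — edges inside the set
over edges crossing its boundary — with two degenerate conventions:
``E_in = 0`` gives 0, and ``E_out = 0`` with ``E_in > 0`` gives ``+inf``
(a whole connected component; ordered above every finite score).

After growth the cluster is *culled* to a fixed point (any member whose
removal improves modularity by more than the ``msp`` margin is dropped,
rescanning after each removal), optionally *trimmed* (a single simultaneous
pass removing members with fewer than 2 intra-cluster edges), and then
*merged* into the first previously produced cluster it overlaps by at least
``mp`` of the smaller of the two (set union, statistics recomputed, no
re-growth).  Clusters smaller than ``min_size`` are discarded at the end.

All orderings (seed order, queue insertion, cull scan) are deterministic:
descending weight with lexicographic tie-break for seeds and queue
insertion, lexicographic for the cull scan.  Identical inputs and
parameters therefore yield identical output.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .weighting import VertexWeights, compute_vertex_weights

__all__ = [
    "Cluster",
    "ClusteringParams",
    "local_modularity",
    "score_cluster",
    "grow_cluster",
    "trim_cluster",
    "maybe_merge",
    "run_mine",
    "cluster_from_members",
]


@dataclass(frozen=True)
class ClusteringParams:
    """Tunable parameters of the clustering pipeline.

    vwp : vertex weight percentage in [0, 1] — a candidate passes the weight
        test when its weight is at least ``(1 - vwp)`` times the weight of
        the member that enqueued it (1.0 disables the test, 0.0 requires
        candidates to match their source's weight).
    msp : modularity score percentage in [0, 1] — the relative tolerance /
        improvement margin on local modularity used for admission, rejection
        and culling.
    mp : merge percentage in (0, 1] — clusters overlapping an earlier cluster
        by at least this fraction of the smaller cluster are merged into it.
    trim : drop members with fewer than 2 intra-cluster edges (haircut).
    min_size : minimum size of a reported cluster.

    Defaults are the setting found to balance modularity and accuracy on a
    dense metazoan interactome (vwp=0.9, msp=0.3, trim on), with merging at
    50% overlap and size-1/2 clusters filtered out.
    """

    vwp: float = 0.9
    msp: float = 0.3
    mp: float = 0.5
    trim: bool = True
    min_size: int = 3

    def __post_init__(self):
        if not 0.0 <= self.vwp <= 1.0:
            raise ValueError(f"vwp must be in [0, 1], got {self.vwp}")
        if not 0.0 <= self.msp <= 1.0:
            raise ValueError(f"msp must be in [0, 1], got {self.msp}")
        if not 0.0 < self.mp <= 1.0:
            raise ValueError(f"mp must be in (0, 1], got {self.mp}")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")


@dataclass(frozen=True)
class Cluster:
    """A predicted module: a member set plus its derived statistics.

    score = density * |members|; local_modularity = E_in / E_out with the
    degenerate conventions described in the module docstring.
    """

    members: frozenset[str]
    seed: str | None
    e_in: int
    e_out: int

    @property
    def density(self) -> float:
        k = len(self.members)
        if k <= 1:
            return 0.0
        return 2.0 * self.e_in / (k * (k - 1))

    @property
    def local_modularity(self) -> float:
        return _mod(self.e_in, self.e_out)

    @property
    def score(self) -> float:
        return self.density * len(self.members)


def _mod(e_in: int, e_out: int) -> float:
    if e_in == 0:
        return 0.0
    if e_out == 0:
        return math.inf
    return e_in / e_out


def _no_decrease(new: float, old: float, msp: float) -> bool:
    # admission criterion A (modularity part): new > old - old*msp.
    # From +inf, any finite score counts as a decrease; inf vs inf is "no
    # change", which the strict comparison rejects at msp = 0.
    if math.isinf(old):
        return math.isinf(new) and msp > 0
    return new > old - old * msp


def _improves(new: float, old: float, msp: float) -> bool:
    # admission criterion B / culling: new > old + old*msp; never from +inf.
    if math.isinf(old):
        return False
    return new > old + old * msp


def _edge_counts(adj: dict[str, set[str]], degree: dict[str, int], members) -> tuple[int, int]:
    e_in = sum(len(adj[v] & members) for v in members) // 2
    e_out = sum(degree[v] for v in members) - 2 * e_in
    return e_in, e_out


def local_modularity(graph: nx.Graph, members) -> float:
    """``E_in / E_out`` for an arbitrary member set of ``graph``."""
    members = set(members)
    for v in members:
        if v not in graph:
            raise KeyError(f"node {v!r} not in graph")
    e_in = e_out = 0
    for v in members:
        for u in graph.adj[v]:
            if u in members:
                e_in += 1
            else:
                e_out += 1
    return _mod(e_in // 2, e_out)


def score_cluster(graph: nx.Graph, cluster: Cluster) -> float:
    """Cluster score ``C_s = density * |members|``."""
    return cluster.score


def cluster_from_members(graph: nx.Graph, members, seed: str | None = None) -> Cluster:
    """Build a :class:`Cluster` with statistics computed against ``graph``."""
    members = frozenset(members)
    for v in members:
        if v not in graph:
            raise KeyError(f"node {v!r} not in graph")
    adj = {v: set(graph.adj[v]) for v in members}
    degree = {v: graph.degree(v) for v in members}
    e_in, e_out = _edge_counts(adj, degree, members)
    return Cluster(members=members, seed=seed, e_in=e_in, e_out=e_out)


class _Workspace:
    """Precomputed adjacency, degrees and queue ordering shared across seeds."""

    def __init__(self, graph: nx.Graph, weights: VertexWeights):
        self.adj = {v: set(graph.adj[v]) for v in graph.nodes()}
        self.degree = {v: len(self.adj[v]) for v in self.adj}
        self.weights = weights
        w = weights.weight
        # descending weight, lexicographic tie-break — used for both seed
        # iteration and queue insertion among a node's neighbours
        self.sorted_neighbors = {
            v: sorted(nbrs, key=lambda u: (-w[u], u)) for v, nbrs in self.adj.items()
        }


def _grow(ws: _Workspace, seed: str, params: ClusteringParams) -> tuple[set[str], int, int]:
    adj, degree, weight = ws.adj, ws.degree, ws.weights.weight
    members = {seed}
    e_in, e_out = 0, degree[seed]
    visited = {seed}
    queue: deque[tuple[str, str]] = deque((n, seed) for n in ws.sorted_neighbors[seed])
    while queue:
        n, source = queue.popleft()
        if n in members or n in visited:
            continue
        visited.add(n)
        e_nc = len(adj[n] & members)
        new_in = e_in + e_nc
        new_out = e_out - e_nc + (degree[n] - e_nc)
        old_mod = _mod(e_in, e_out)
        new_mod = _mod(new_in, new_out)
        admit = (
            weight[n] >= weight[source] * (1.0 - params.vwp)
            and _no_decrease(new_mod, old_mod, params.msp)
        ) or _improves(new_mod, old_mod, params.msp)
        if admit:
            members.add(n)
            e_in, e_out = new_in, new_out
            for nb in ws.sorted_neighbors[n]:
                if nb not in members and nb not in visited:
                    queue.append((nb, n))
    return members, e_in, e_out


def _cull(ws: _Workspace, members: set[str], e_in: int, e_out: int, msp: float):
    # fixed point: rescan in lexicographic order after every removal
    adj, degree = ws.adj, ws.degree
    changed = True
    while changed:
        changed = False
        for v in sorted(members):
            e_vc = len(adj[v] & members)
            new_in = e_in - e_vc
            new_out = e_out + e_vc - (degree[v] - e_vc)
            if _improves(_mod(new_in, new_out), _mod(e_in, e_out), msp):
                members.discard(v)
                e_in, e_out = new_in, new_out
                changed = True
                break
    return members, e_in, e_out


def _trim(ws: _Workspace, members: set[str]) -> set[str]:
    # single simultaneous pass against the pre-pass membership
    doomed = {v for v in members if len(ws.adj[v] & members) < 2}
    return members - doomed


def grow_cluster(
    graph: nx.Graph,
    weights: VertexWeights,
    seed: str,
    params: ClusteringParams,
) -> Cluster:
    """Grow, cull and (optionally) trim a single cluster nucleated at ``seed``.

    The result has not been merged against other clusters and may be smaller
    than ``params.min_size`` (the size filter is applied by :func:`run_mine`).
    """
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in graph")
    ws = _Workspace(graph, weights)
    return _finish_cluster(ws, seed, params)


def _finish_cluster(ws: _Workspace, seed: str, params: ClusteringParams) -> Cluster:
    members, e_in, e_out = _grow(ws, seed, params)
    members, e_in, e_out = _cull(ws, members, e_in, e_out, params.msp)
    if params.trim:
        members = _trim(ws, members)
        e_in, e_out = _edge_counts(ws.adj, ws.degree, members)
    return Cluster(members=frozenset(members), seed=seed, e_in=e_in, e_out=e_out)


def trim_cluster(graph: nx.Graph, cluster: Cluster) -> Cluster:
    """Haircut: one simultaneous pass removing members with < 2 intra-cluster
    edges (degree measured inside the cluster-induced subgraph)."""
    members = set(cluster.members)
    adj = {v: set(graph.adj[v]) for v in members}
    doomed = {v for v in members if len(adj[v] & members) < 2}
    return cluster_from_members(graph, members - doomed, seed=cluster.seed)


def _overlap_fraction(a: frozenset[str], b: frozenset[str]) -> float:
    smaller = min(len(a), len(b))
    if smaller == 0:
        return 0.0
    return len(a & b) / smaller


def maybe_merge(
    existing: list[Cluster],
    candidate: Cluster,
    mp: float,
    graph: nx.Graph | None = None,
    _ws: _Workspace | None = None,
) -> list[Cluster]:
    """Merge ``candidate`` into the first cluster of ``existing`` (creation
    order) it overlaps by >= ``mp`` of the smaller cluster, else append it.

    Merging takes the set union and recomputes statistics; the merged cluster
    is not re-grown, and earlier clusters are not rescanned retroactively.
    The list is modified in place and returned.
    """
    for i, cluster in enumerate(existing):
        if _overlap_fraction(cluster.members, candidate.members) >= mp:
            union = cluster.members | candidate.members
            if _ws is not None:
                e_in, e_out = _edge_counts(_ws.adj, _ws.degree, union)
                existing[i] = Cluster(
                    members=frozenset(union), seed=cluster.seed, e_in=e_in, e_out=e_out
                )
            else:
                if graph is None:
                    raise ValueError("maybe_merge needs the graph to recompute statistics")
                existing[i] = cluster_from_members(graph, union, seed=cluster.seed)
            return existing
    existing.append(candidate)
    return existing


def run_mine(graph: nx.Graph, params: ClusteringParams | None = None) -> list[Cluster]:
    """Run the full clustering pipeline on ``graph``.

    Every node is inspected as a seed in descending weight order (ties broken
    lexicographically); each grown cluster passes through culling, optional
    trimming and merge-or-append; clusters smaller than ``params.min_size``
    are then discarded.  Clusters are non-exclusive: a node may appear in
    several.  Output is sorted by score descending (ties: size descending,
    then lexicographically smallest member).
    """
    if params is None:
        params = ClusteringParams()
    if graph.number_of_nodes() == 0:
        return []
    weights = compute_vertex_weights(graph)
    ws = _Workspace(graph, weights)
    seeds = sorted(graph.nodes(), key=lambda v: (-weights.weight[v], v))
    clusters: list[Cluster] = []
    for seed in seeds:
        candidate = _finish_cluster(ws, seed, params)
        maybe_merge(clusters, candidate, params.mp, _ws=ws)
    kept = [c for c in clusters if len(c.members) >= params.min_size]
    kept.sort(key=lambda c: (-c.score, -len(c.members), min(c.members)))
    return kept
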