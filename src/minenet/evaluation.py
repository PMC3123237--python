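"""Validation statistics: enrichment matching, recall/precision, geometric
accuracy, composite modularity, and basic network statistics.

Predicted clusters are matched against annotated gene sets (protein
complexes or GO terms) with a one-sided hypergeometric test: the universe is
the node set of the input network, successes are the annotated members
present in the network, draws are the cluster members.  For each annotated
set the cluster with the smallest p-value is selected; the match counts only
at ``p <= alpha`` (0.05 by default).  Recall ``TP/(TP+FN)`` and precision
``TP/(TP+FP)`` are computed for that cluster, and geometric accuracy is
their geometric mean ``sqrt(R * P)``.

The composite (global) modularity aggregates every cluster's internal and
boundary edges against the network total, in the Newman–Girvan community
form::

    Q = sum_c [ E_cIn / E_total  -  ((2 E_cIn + E_cOut) / (2 E_total))^2 ]

Only clusters fully contained in the main (largest) connected component
enter the sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
from scipy.stats import hypergeom

from .clustering import Cluster
from .graph_io import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "EvaluationSummary",
    "NetworkStats",
    "hypergeom_overlap_pvalue",
    "geometric_accuracy",
    "match_complexes",
    "summarize",
    "evaluate_clusters",
    "global_modularity",
    "network_stats",
]


@dataclass(frozen=True)
class MatchResult:
    """Best-cluster match for one annotated set.

    ``best_cluster`` is the index into the cluster list, or ``None`` when no
    cluster reaches ``p <= alpha``; ``overlap`` is the true-positive count
    against the annotated set restricted to network members.
    """

    complex_id: str
    best_cluster: int | None
    overlap: int
    p_value: float
    recall: float
    precision: float

    @property
    def geometric_accuracy(self) -> float:
        return math.sqrt(self.recall * self.precision)


@dataclass(frozen=True)
class EvaluationSummary:
    mean_recall: float
    mean_precision: float
    mean_geometric_accuracy: float
    global_modularity: float
    n_clusters: int
    n_complexes: int
    n_matched: int
    mean_cluster_size: float
    mean_cluster_density: float


class NetworkStats(NamedTuple):
    density: float
    characteristic_path_length: float


def hypergeom_overlap_pvalue(
    population: int, complex_size: int, cluster_size: int, overlap: int
) -> float:
    """Upper-tail hypergeometric probability ``P(X >= overlap)``.

    ``X`` counts annotated members drawn when ``cluster_size`` nodes are
    sampled without replacement from a universe of ``population`` nodes of
    which ``complex_size`` are annotated.
    """
    if not (
        0 <= overlap <= min(complex_size, cluster_size)
        and 0 <= complex_size <= population
        and 0 <= cluster_size <= population
    ):
        raise ValueError(
            f"invalid hypergeometric arguments: population={population}, "
            f"complex={complex_size}, cluster={cluster_size}, overlap={overlap}"
        )
    p = float(hypergeom.sf(overlap - 1, population, complex_size, cluster_size))
    return min(max(p, 0.0), 1.0)


def geometric_accuracy(recall: float, precision: float) -> float:
    """Geometric mean ``sqrt(R * P)`` of recall and precision."""
    if not (0.0 <= recall <= 1.0 and 0.0 <= precision <= 1.0):
        raise ValueError(f"recall/precision must be in [0, 1]: {recall}, {precision}")
    return math.sqrt(recall * precision)


def match_complexes(
    clusters: Sequence[Cluster],
    annotations: AnnotationSet,
    graph: nx.Graph,
    alpha: float = 0.05,
) -> list[MatchResult]:
    """Match every annotated set to its most significantly overlapping cluster.

    Each annotated set is first restricted to members present in the network;
    sets with no member in the network are excluded (and logged).  Among
    clusters the smallest p-value wins, with ties broken by larger overlap,
    then smaller cluster, then lower cluster index.  A match is recorded only
    at ``p <= alpha``; unmatched sets report recall = precision = 0 and
    ``best_cluster = None``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    population = graph.number_of_nodes()
    nodes = set(graph.nodes())
    results: list[MatchResult] = []
    for complex_id, members in annotations.sets.items():
        restricted = members & nodes
        if not restricted:
            logger.info(
                "complex %s has no members in the network; excluded", complex_id
            )
            continue
        best: tuple[float, int, int, int] | None = None  # (p, -overlap, size, idx)
        for idx, cluster in enumerate(clusters):
            overlap = len(restricted & cluster.members)
            p = hypergeom_overlap_pvalue(
                population, len(restricted), len(cluster.members), overlap
            )
            key = (p, -overlap, len(cluster.members), idx)
            if best is None or key < best:
                best = key
        if best is not None and best[0] <= alpha:
            p, neg_overlap, cluster_size, idx = best
            tp = -neg_overlap
            results.append(
                MatchResult(
                    complex_id=complex_id,
                    best_cluster=idx,
                    overlap=tp,
                    p_value=p,
                    recall=tp / len(restricted),
                    precision=tp / cluster_size,
                )
            )
        else:
            results.append(
                MatchResult(
                    complex_id=complex_id,
                    best_cluster=None,
                    overlap=0,
                    p_value=1.0 if best is None else best[0],
                    recall=0.0,
                    precision=0.0,
                )
            )
    return results


def summarize(
    matches: Iterable[MatchResult],
    clusters: Sequence[Cluster],
    graph: nx.Graph,
    include_unmatched: bool = False,
) -> EvaluationSummary:
    """Aggregate per-complex matches into summary means.

    By default only complexes with a significant match contribute to the mean
    recall/precision/geometric accuracy; with ``include_unmatched=True``
    unmatched complexes count as zeros (sensitivity analysis).  Means over an
    empty contributor set are reported as NaN.
    """
    matches = list(matches)
    contributors = [
        m for m in matches if include_unmatched or m.best_cluster is not None
    ]
    n_matched = sum(1 for m in matches if m.best_cluster is not None)

    def _mean(values: list[float]) -> float:
        return sum(values) / len(values) if values else math.nan

    return EvaluationSummary(
        mean_recall=_mean([m.recall for m in contributors]),
        mean_precision=_mean([m.precision for m in contributors]),
        mean_geometric_accuracy=_mean(
            [m.geometric_accuracy for m in contributors]
        ),
        global_modularity=global_modularity(graph, clusters),
        n_clusters=len(clusters),
        n_complexes=len(matches),
        n_matched=n_matched,
        mean_cluster_size=_mean([float(len(c.members)) for c in clusters]),
        mean_cluster_density=_mean([c.density for c in clusters]),
    )


def evaluate_clusters(
    clusters: Sequence[Cluster],
    annotations: AnnotationSet,
    graph: nx.Graph,
    alpha: float = 0.05,
    include_unmatched: bool = False,
) -> tuple[list[MatchResult], EvaluationSummary]:
    """Convenience wrapper: match complexes and summarize in one call."""
    matches = match_complexes(clusters, annotations, graph, alpha=alpha)
    return matches, summarize(matches, clusters, graph, include_unmatched)


def global_modularity(graph: nx.Graph, clusters: Sequence[Cluster]) -> float:
    """Composite modularity over all clusters contained in the main component.

    ``Q = sum_c [E_cIn/E_total - ((2 E_cIn + E_cOut)/(2 E_total))^2]``;
    0.0 for an empty cluster list or an edgeless graph.
    """
    e_total = graph.number_of_edges()
    if e_total == 0 or not clusters:
        return 0.0
    components = list(nx.connected_components(graph))
    main = max(components, key=lambda c: (len(c), min(c)))
    q = 0.0
    for cluster in clusters:
        if not cluster.members or not cluster.members <= main:
            continue
        q += cluster.e_in / e_total - (
            (2 * cluster.e_in + cluster.e_out) / (2 * e_total)
        ) ** 2
    return q


def network_stats(graph: nx.Graph) -> NetworkStats:
    """Whole-network density and characteristic path length.

    Density is ``2|E| / (|V| (|V|-1))``.  The characteristic path length is
    the mean shortest-path length over all connected unordered node pairs;
    disconnected pairs are excluded, and the value is NaN when no connected
    pair exists (or |V| < 2).
    """
    n = graph.number_of_nodes()
    if n < 2:
        return NetworkStats(0.0, math.nan)
    density = 2.0 * graph.number_of_edges() / (n * (n - 1))
    total = 0
    pairs = 0
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        sub = graph.subgraph(component)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    # each unordered pair counted twice above
    if pairs == 0:
        return NetworkStats(density, math.nan)
    return NetworkStats(density, total / pairs)
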