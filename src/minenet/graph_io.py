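"""Network and gene-set I/O and the canonical graph data model.

Interaction networks are held as :class:`networkx.Graph` objects — simple,
undirected, unweighted.  Node identifiers are the raw string tokens from the
input file, case-sensitive; any identifier mapping belongs upstream of this
package.  Self-loops are dropped and duplicate edges collapse, both within a
file and across files when several inputs are unioned.

Supported formats:

* SIF (Cytoscape simple interaction format): ``nodeA <type> nodeB [nodeC ...]``,
  tab-delimited if the line contains a tab, otherwise whitespace-delimited.
  A bare single-token line declares an isolated node.
* Two-column tab-separated edge lists: ``nodeA<TAB>nodeB``.
* GMT (Broad gene-set format) and two-column ``setID<TAB>gene`` dumps for
  annotation sets (protein complexes, GO term memberships).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "AnnotationSet",
    "read_network",
    "read_gmt",
    "read_gene_set_tsv",
    "write_network_tsv",
    "write_gmt",
    "write_clusters",
    "read_clusters",
]


class ParseError(ValueError):
    """Malformed line in an input file; carries the file path and line number."""

    def __init__(self, path: str | PathLike, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{line_no}: {message}")


@dataclass
class AnnotationSet:
    """Named gene sets (annotated complexes or GO terms) used as a gold standard.

    ``sets`` maps a unique set identifier to its member genes; ``descriptions``
    optionally carries the free-text description column of a GMT file.
    """

    name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _infer_format(path: Path) -> str:
    return "sif" if path.suffix.lower() == ".sif" else "tsv"


def _parse_sif_line(graph: nx.Graph, tokens: list[str], path, line_no: int) -> None:
    if len(tokens) == 1:
        graph.add_node(tokens[0])
        return
    if len(tokens) == 2:
        raise ParseError(path, line_no, "SIF line has 2 columns; expected 1 or >= 3")
    source = tokens[0]
    graph.add_node(source)
    for target in tokens[2:]:
        if target != source:
            graph.add_edge(source, target)
        else:
            graph.add_node(source)


def read_network(
    paths: str | PathLike | Sequence[str | PathLike],
    format: str | None = None,
) -> nx.Graph:
    """Read one or more interaction files and return their union as a graph.

    Parameters
    ----------
    paths
        A single path or a sequence of paths.  When several files are given
        their node and edge sets are unioned; duplicate edges collapse.
    format
        ``"sif"``, ``"tsv"``, or ``None`` to infer from the extension
        (``.sif`` -> SIF, anything else -> TSV) per file.

    Raises
    ------
    ParseError
        On a line with the wrong column count for the declared format.
    """
    if isinstance(paths, (str, PathLike)):
        paths = [paths]
    graph = nx.Graph()
    for raw_path in paths:
        path = Path(raw_path)
        fmt = format or _infer_format(path)
        if fmt not in ("sif", "tsv"):
            raise ValueError(f"unknown network format: {fmt!r}")
        with open(path, encoding="utf-8") as handle:
            for line_no, line in enumerate(handle, start=1):
                line = line.rstrip("\n").rstrip("\r")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                if fmt == "sif":
                    tokens = line.split("\t") if "\t" in line else line.split()
                    tokens = [t for t in tokens if t]
                    _parse_sif_line(graph, tokens, path, line_no)
                else:
                    tokens = line.split("\t")
                    if len(tokens) != 2 or not tokens[0] or not tokens[1]:
                        raise ParseError(
                            path, line_no, "TSV edge line must have exactly 2 columns"
                        )
                    a, b = tokens
                    if a == b:
                        graph.add_node(a)
                    else:
                        graph.add_edge(a, b)
    return graph


def read_gmt(
    path: str | PathLike, min_size: int = 3, max_size: int = 100
) -> AnnotationSet:
    """Read a GMT gene-set file, keeping sets with ``min_size <= |set| <= max_size``.

    Each line is ``setID<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line collapse to one member before the size filter.
    """
    path = Path(path)
    annotation = AnnotationSet(name=path.stem)
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, line_no, "GMT line must have >= 3 fields")
            set_id, description = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not min_size <= len(members) <= max_size:
                logger.debug(
                    "excluding set %s (size %d outside [%d, %d])",
                    set_id, len(members), min_size, max_size,
                )
                continue
            annotation.sets[set_id] = members
            annotation.descriptions[set_id] = description
    return annotation


def read_gene_set_tsv(
    path: str | PathLike, min_size: int = 3, max_size: int = 100
) -> AnnotationSet:
    """Read a two-column ``setID<TAB>gene`` membership dump (MIPS-style).

    Rows sharing a set identifier accumulate into one set; the same size
    filter as :func:`read_gmt` applies afterwards.
    """
    path = Path(path)
    raw: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(path, line_no, "expected setID<TAB>gene")
            set_id, gene = fields
            if set_id not in raw:
                raw[set_id] = set()
                order.append(set_id)
            raw[set_id].add(gene)
    annotation = AnnotationSet(name=path.stem)
    for set_id in order:
        members = frozenset(raw[set_id])
        if min_size <= len(members) <= max_size:
            annotation.sets[set_id] = members
            annotation.descriptions[set_id] = ""
    return annotation


def write_network_tsv(
    graph: nx.Graph, path: str | PathLike, header_comments: Iterable[str] = ()
) -> None:
    """Write a graph as a two-column edge list; isolated nodes are appended
    as self-pair lines so a round trip preserves the node set.  Optional
    ``header_comments`` are emitted first as ``#`` lines (skipped on read)."""
    with open(path, "w", encoding="utf-8") as handle:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{a}\t{b}\n")
        for node in sorted(n for n in graph.nodes() if graph.degree(n) == 0):
            handle.write(f"{node}\t{node}\n")


def write_gmt(annotation: AnnotationSet, path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for set_id, members in annotation.sets.items():
            description = annotation.descriptions.get(set_id, "")
            genes = "\t".join(sorted(members))
            handle.write(f"{set_id}\t{description}\t{genes}\n")


def _format_mod(value: float) -> str:
    return "inf" if value == float("inf") else f"{value:.6g}"


def write_clusters(
    clusters: Iterable,
    path: str | PathLike,
    header_comments: Iterable[str] = (),
) -> None:
    """Write a tab-separated cluster report.

    One row per cluster: 1-based rank (score descending, ties by size
    descending then lexicographically smallest member), score, size, local
    modularity (``inf`` sentinel when no boundary edges), density, and the
    semicolon-joined, sorted member list.  ``header_comments`` lines (for the
    run manifest / parameter record) are emitted first, prefixed with ``#``.
    """
    ranked = sorted(
        clusters,
        key=lambda c: (-c.score, -len(c.members), min(c.members) if c.members else ""),
    )
    with open(path, "w", encoding="utf-8") as handle:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        handle.write("# rank\tscore\tsize\tlocal_modularity\tdensity\tmembers\n")
        for rank, cluster in enumerate(ranked, start=1):
            members = ";".join(sorted(cluster.members))
            handle.write(
                f"{rank}\t{cluster.score:.6g}\t{len(cluster.members)}\t"
                f"{_format_mod(cluster.local_modularity)}\t"
                f"{cluster.density:.6g}\t{members}\n"
            )


def read_clusters(path: str | PathLike) -> list[frozenset[str]]:
    """Read member sets back from a cluster report written by
    :func:`write_clusters` (rank order preserved)."""
    out: list[frozenset[str]] = []
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(path, line_no, "cluster row must have 6 columns")
            out.append(frozenset(m for m in fields[5].split(";") if m))
    return out
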