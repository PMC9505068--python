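"""Background protein–protein interaction network: loading, cleaning, queries.

The interactome is an undirected simple graph over opaque, case-sensitive
protein identifiers. Published PPI edge lists routinely contain self-loops
and duplicate (or reversed-duplicate) rows; these are dropped at load time
but counted in a :class:`LoadReport` so the cleaning is auditable.

All distance queries are exact unweighted shortest-path lengths (BFS).
Separation analyses should be run on the largest connected component so
that every pairwise distance is finite; see
:func:`largest_connected_component`.
"""

from __future__ import annotations

import io
import logging
import os
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "ProteinSet",
    "MappedSet",
    "LoadReport",
    "load_edge_list",
    "largest_connected_component",
    "map_protein_set",
    "nearest_distance_to_set",
    "nearest_distances_from_sources",
]

#: lowercase tokens recognised as column headers in edge-list files
_HEADER_TOKENS = {
    "source", "target", "protein1", "protein2", "proteina", "proteinb",
    "node1", "node2", "from", "to", "genea", "geneb", "gene1", "gene2",
    "interactor_a", "interactor_b",
}


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from :func:`load_edge_list`."""

    n_rows: int
    n_nodes: int
    n_edges: int
    n_self_loops: int
    n_duplicate_edges: int


@dataclass(frozen=True)
class ProteinSet:
    """A labelled set of protein identifiers (e.g. a drug-disposition module
    or the target list of one herbal component)."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"protein set {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MappedSet:
    """A protein set restricted to the nodes of a given interactome.

    ``kept`` and ``dropped`` partition the original members.
    """

    source: str
    kept: frozenset[str]
    dropped: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "kept", frozenset(self.kept))
        object.__setattr__(self, "dropped", frozenset(self.dropped))
        if not self.kept:
            raise ValueError(f"set {self.source!r} has no mapped members")
        if self.kept & self.dropped:
            raise ValueError("kept and dropped overlap")

    def __len__(self) -> int:
        return len(self.kept)


@dataclass
class Interactome:
    """Undirected simple protein–protein interaction graph.

    Wraps a :class:`networkx.Graph`; the invariants (no self-loops, no
    parallel edges) are enforced on construction.
    """

    graph: nx.Graph
    provenance: str = ""
    report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def _open_maybe(source: str | os.PathLike | TextIO) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "r", encoding="utf-8"), True


def load_edge_list(
    source: str | os.PathLike | TextIO,
    comment_prefix: str = "#",
    provenance: str | None = None,
) -> Interactome:
    """Read a two-column (tab- or whitespace-separated) edge list.

    Self-loops are discarded and duplicate / reversed-duplicate edges
    collapsed; both are counted in the returned interactome's ``report``.
    A single header row is tolerated when both leading fields are common
    column names (``source``/``target`` etc.).

    Raises
    ------
    ValueError
        On empty input, or on a data row with fewer than two non-empty
        fields (the message names the offending line number).
    """
    handle, close = _open_maybe(source)
    if provenance is None:
        provenance = getattr(source, "name", None) or str(source)
    g = nx.Graph()
    n_rows = n_loops = n_dups = 0
    try:
        first_data = True
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or (comment_prefix and line.startswith(comment_prefix)):
                continue
            fields = [f for f in line.replace("\t", " ").split() if f]
            if first_data:
                first_data = False
                if (
                    len(fields) >= 2
                    and fields[0].lower() in _HEADER_TOKENS
                    and fields[1].lower() in _HEADER_TOKENS
                ):
                    continue
            if len(fields) < 2:
                raise ValueError(
                    f"malformed edge-list row at line {lineno}: {raw.rstrip()!r}"
                )
            u, v = fields[0], fields[1]
            n_rows += 1
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
    finally:
        if close:
            handle.close()
    if n_rows == 0:
        raise ValueError("edge list contains no data rows")
    report = LoadReport(
        n_rows=n_rows,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_self_loops=n_loops,
        n_duplicate_edges=n_dups,
    )
    logger.info(
        "loaded %d nodes / %d edges (%d self-loops and %d duplicates dropped)",
        report.n_nodes, report.n_edges, n_loops, n_dups,
    )
    return Interactome(graph=g, provenance=provenance, report=report)


def largest_connected_component(g: Interactome) -> Interactome:
    """Restrict to the maximum-cardinality connected component.

    Ties between equally large components are broken by the
    lexicographically smallest member identifier, so the result is
    deterministic.
    """
    if g.n_nodes == 0:
        raise ValueError("interactome is empty")
    best = min(nx.connected_components(g.graph), key=lambda c: (-len(c), min(c)))
    sub = g.graph.subgraph(best).copy()
    return Interactome(graph=sub, provenance=f"{g.provenance} (LCC)", report=g.report)


def map_protein_set(g: Interactome, s: ProteinSet) -> MappedSet:
    """Intersect a protein set with the interactome's node set.

    Members absent from the network are recorded in ``dropped`` and logged;
    an entirely unmapped set is an error.
    """
    kept = frozenset(m for m in s.members if m in g.graph)
    dropped = frozenset(s.members) - kept
    if not kept:
        raise ValueError(f"protein set {s.label!r} has no mapped members")
    if dropped:
        logger.info(
            "set %r: %d of %d members not in network: %s",
            s.label, len(dropped), len(s.members), ", ".join(sorted(dropped)),
        )
    return MappedSet(source=s.label, kept=kept, dropped=dropped)


def _require_nodes(g: Interactome, nodes: Iterable[str]) -> None:
    missing = [n for n in nodes if n not in g.graph]
    if missing:
        raise ValueError(f"identifiers not in network: {sorted(missing)}")


def nearest_distances_from_sources(
    g: Interactome, sources: Iterable[str]
) -> Mapping[str, int]:
    """Multi-source BFS: for every reachable node, the unweighted
    shortest-path distance to the nearest source (0 for sources)."""
    sources = set(sources)
    if not sources:
        raise ValueError("sources is empty")
    _require_nodes(g, sources)
    adj = g.graph.adj
    dist: dict[str, int] = {s: 0 for s in sources}
    queue: deque[str] = deque(sources)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def nearest_distance_to_set(
    g: Interactome, sources: Iterable[str], query: str
) -> int:
    """Unweighted shortest-path distance from ``query`` to the nearest
    member of ``sources`` (0 when the query is itself a source).

    Raises
    ------
    ValueError
        When no source is reachable; the message recommends restricting
        the analysis to the largest connected component.
    """
    sources = set(sources)
    if not sources:
        raise ValueError("sources is empty")
    _require_nodes(g, sources | {query})
    if query in sources:
        return 0
    adj = g.graph.adj
    seen = {query}
    queue: deque[tuple[str, int]] = deque([(query, 0)])
    while queue:
        u, du = queue.popleft()
        for v in adj[u]:
            if v in sources:
                return du + 1
            if v not in seen:
                seen.add(v)
                queue.append((v, du + 1))
    raise ValueError(
        f"no member of the source set is reachable from {query!r}; "
        "restrict the analysis to the largest connected component "
        "(see largest_connected_component)"
    )
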