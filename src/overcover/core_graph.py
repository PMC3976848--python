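"""Graph and cover data model plus readers/writers.

Networks are plain :class:`networkx.Graph` objects restricted to the simple,
undirected, unweighted case; node ids are opaque strings.  A *cover* is the
overlapping analogue of a partition: an ordered collection of member sets in
which a node may appear more than once, plus the set of nodes the chain rule
excluded from every community.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "NodeState",
    "Cover",
    "read_edge_list",
    "read_gml",
    "write_edge_list",
    "graph_density",
    "read_cover",
    "write_cover",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a cover and a network disagree."""


@dataclass
class NodeState:
    """Per-node flags driving the detection algorithm's pruning.

    ``is_located`` implies ``is_visited``; an isolated node is a member of no
    community (chain effect).
    """

    is_visited: bool = False
    is_located: bool = False
    is_isolated: bool = False

    def locate(self) -> None:
        self.is_visited = True
        self.is_located = True


class Cover:
    """An overlapping node-to-community assignment.

    Communities are held in insertion order under stable string ids; a
    node-to-community index is maintained incrementally so overlap lookups
    are O(1).
    """

    def __init__(self) -> None:
        self.communities: dict[str, set[str]] = {}
        self.node_index: dict[str, set[str]] = {}
        self.isolated: set[str] = set()

    # -- construction ----------------------------------------------------

    def add_community(self, members: Iterable[str], cid: str | None = None) -> str:
        if cid is None:
            cid = f"C{len(self.communities) + 1}"
        if cid in self.communities:
            raise ValueError(f"duplicate community id {cid!r}")
        self.communities[cid] = set()
        for node in members:
            self.add_member(cid, node)
        return cid

    def add_member(self, cid: str, node: str) -> None:
        self.communities[cid].add(node)
        self.node_index.setdefault(node, set()).add(cid)
        self.isolated.discard(node)

    def remove_member(self, cid: str, node: str) -> None:
        self.communities[cid].discard(node)
        ids = self.node_index.get(node)
        if ids is not None:
            ids.discard(cid)
            if not ids:
                del self.node_index[node]

    def drop_community(self, cid: str) -> set[str]:
        members = self.communities.pop(cid)
        for node in members:
            ids = self.node_index[node]
            ids.discard(cid)
            if not ids:
                del self.node_index[node]
        return members

    # -- queries ---------------------------------------------------------

    def communities_of(self, node: str) -> set[str]:
        return set(self.node_index.get(node, set()))

    def membership_number(self, node: str) -> int:
        return len(self.node_index.get(node, ()))

    def overlap_nodes(self) -> set[str]:
        return {v for v, ids in self.node_index.items() if len(ids) >= 2}

    def covered_nodes(self) -> set[str]:
        return set(self.node_index)

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self) -> Iterator[str]:
        return iter(self.communities)

    def copy(self) -> "Cover":
        dup = Cover()
        for cid, members in self.communities.items():
            dup.add_community(sorted(members), cid=cid)
        dup.isolated = set(self.isolated)
        return dup

    def validate(self, net: nx.Graph) -> None:
        unknown = self.covered_nodes() | self.isolated
        unknown -= set(net.nodes)
        if unknown:
            raise ValidationError(
                f"cover references nodes absent from the network: {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(source: IO[str] | Iterable[str], comment_prefix: str = "#") -> nx.Graph:
    """Read a two-column whitespace-separated edge list into a simple graph.

    Duplicate lines (in either orientation) collapse to one edge and
    self-loops are dropped with a warning.  A line with more or fewer than two
    tokens — including a third weight column — is a :class:`ParseError`.
    """
    net = nx.Graph()
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(comment_prefix):
            continue
        tokens = stripped.split()
        if len(tokens) != 2:
            raise ParseError(
                f"line {lineno}: expected two node ids, got {len(tokens)} tokens"
            )
        u, v = tokens
        if u == v:
            logger.warning("line %d: dropping self-loop on node %r", lineno, u)
            net.add_node(u)
            continue
        net.add_edge(u, v)
    return net


def read_gml(source: IO[str] | str) -> nx.Graph:
    """Read a GML node/edge description into a simple undirected graph.

    Node ``label`` keys are preferred as ids when present; otherwise the
    numeric ``id`` keys are stringified.
    """
    text = source if isinstance(source, str) else source.read()

    def parse(body: str) -> nx.Graph:
        try:
            return nx.parse_gml(body, label="label")
        except nx.NetworkXError:
            return nx.parse_gml(body, label="id")

    try:
        parsed = parse(text)
    except nx.NetworkXError as exc:
        if "duplicated" in str(exc):
            # re-read duplicate edge blocks as a multigraph, then collapse
            relaxed = re.sub(r"graph\s*\[", "graph [ multigraph 1 ", text, count=1)
            try:
                parsed = parse(relaxed)
            except nx.NetworkXError as exc2:
                raise ParseError(f"invalid GML: {exc2}") from exc2
        else:
            raise ParseError(f"invalid GML: {exc}") from exc
    net = nx.Graph()
    net.add_nodes_from(str(v) for v in parsed.nodes)
    for u, v in parsed.edges():
        u, v = str(u), str(v)
        if u == v:
            logger.warning("dropping self-loop on node %r", u)
            continue
        net.add_edge(u, v)
    return net


def write_edge_list(net: nx.Graph, sink: IO[str]) -> None:
    """Write one ``u v`` line per edge, lexicographically sorted."""
    for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
        sink.write(f"{u} {v}\n")


def graph_density(net: nx.Graph) -> float:
    """Fraction of node pairs joined by an edge, ``2m / (n(n-1))``."""
    if net.number_of_nodes() < 2:
        raise ValueError("graph density needs at least two nodes")
    return nx.density(net)


def write_cover(cover: Cover, sink: IO[str]) -> None:
    """One line per community: ``<id>\\t<members sorted, space-separated>``.

    Isolated nodes, if any, go on a trailing ``#isolated`` line.
    """
    for cid, members in cover.communities.items():
        sink.write(f"{cid}\t{' '.join(sorted(members))}\n")
    if cover.isolated:
        sink.write(f"#isolated\t{' '.join(sorted(cover.isolated))}\n")


def read_cover(source: IO[str] | Iterable[str], net: nx.Graph | None = None) -> Cover:
    """Inverse of :func:`write_cover`; validates node ids against ``net`` if given."""
    cover = Cover()
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split("\t")
        if len(fields) == 1:  # tolerate space-only separation after the id
            fields = stripped.split(None, 1)
        if not fields:
            continue
        cid, rest = fields[0], (fields[1] if len(fields) > 1 else "")
        members = rest.split()
        if cid == "#isolated":
            cover.isolated.update(members)
            continue
        if cid.startswith("#"):
            continue
        if not members:
            raise ParseError(f"line {lineno}: community {cid!r} has no members")
        cover.add_community(members, cid=cid)
    if net is not None:
        cover.validate(net)
    return cover
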