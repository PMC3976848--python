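"""Synthetic benchmark graphs and the bundled karate-club network.

The planted-overlap generator emulates networks with known overlapping
community structure: dense intra-block wiring, sparse inter-block noise, and
a small designated set of nodes wired into two or more blocks as ground-truth
overlaps.  Degenerate structures (clique, ring, chain) used in the method's
arguments are provided as well.  All generators are pure functions of their
arguments plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np

from .core_graph import Cover, read_edge_list

__all__ = [
    "PlantedSpec",
    "make_clique",
    "make_ring",
    "make_chain",
    "make_planted_overlap",
    "karate_fixture",
]


def _str_graph(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes}, copy=True)


def make_clique(n: int) -> nx.Graph:
    """Complete graph K_n with n(n-1)/2 edges; nodes "0".."n-1"."""
    if n < 3:
        raise ValueError("clique needs n >= 3")
    return _str_graph(nx.complete_graph(n))


def make_ring(n: int) -> nx.Graph:
    """Cycle C_n with n edges, every node of degree 2."""
    if n < 3:
        raise ValueError("ring needs n >= 3")
    return _str_graph(nx.cycle_graph(n))


def make_chain(n: int) -> nx.Graph:
    """Path P_n with n-1 edges and two degree-1 endpoints."""
    if n < 2:
        raise ValueError("chain needs n >= 2")
    return _str_graph(nx.path_graph(n))


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted overlapping-block graph.

    ``overlap_assignments`` maps node ids (strings "0", "1", ...) to the set
    of block indices the node is planted into; such nodes are wired into every
    assigned block with probability ``p_in``.  Defaults reflect networks with
    evident structure: near-saturated blocks, 2% background noise, and an
    overlap fraction well under 10% of nodes.
    """

    block_sizes: tuple[int, ...] = (10, 10, 10)
    p_in: float = 0.9
    p_out: float = 0.02
    overlap_assignments: dict[str, frozenset[int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for node, blocks in self.overlap_assignments.items():
            if len(blocks) < 2:
                raise ValueError(f"overlap node {node!r} must be in >= 2 blocks")
            if any(b >= len(self.block_sizes) for b in blocks):
                raise ValueError(f"overlap node {node!r} names an unknown block")


def default_overlap_spec(
    block_sizes: tuple[int, ...] = (10, 10, 10),
    n_overlap: int = 2,
    p_in: float = 0.9,
    p_out: float = 0.02,
    seed: int = 0,
) -> PlantedSpec:
    """A PlantedSpec where the first node of block j also belongs to block j+1.

    Each of the ``n_overlap`` overlap nodes straddles exactly two blocks,
    mirroring the small overlap fractions seen in real networks.
    """
    n_blocks = len(block_sizes)
    if n_overlap > n_blocks:
        raise ValueError("at most one planted overlap node per block")
    offsets = [sum(block_sizes[:j]) for j in range(n_blocks)]
    assignments = {
        str(offsets[j]): frozenset({j, (j + 1) % n_blocks}) for j in range(n_overlap)
    }
    return PlantedSpec(
        block_sizes=block_sizes,
        p_in=p_in,
        p_out=p_out,
        overlap_assignments=assignments,
        seed=seed,
    )


def make_planted_overlap(spec: PlantedSpec) -> tuple[nx.Graph, Cover]:
    """Draw a planted overlapping-block graph and its ground-truth cover.

    Each within-block pair is linked with probability ``p_in``, cross-block
    pairs with ``p_out``; overlap nodes are wired into every assigned block at
    ``p_in``.  An overlap node that comes out with fewer than two edges into a
    block gets its intra-block edges redrawn until it is anchored.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [str(i) for i in range(sum(spec.block_sizes))]
    blocks: list[set[str]] = []
    start = 0
    for size in spec.block_sizes:
        blocks.append(set(nodes[start : start + size]))
        start += size
    for node, assigned in spec.overlap_assignments.items():
        for b in assigned:
            blocks[b].add(node)

    membership: dict[str, set[int]] = {v: set() for v in nodes}
    for b, members in enumerate(blocks):
        for v in members:
            membership[v].add(b)

    net = nx.Graph()
    net.add_nodes_from(nodes)
    order = sorted(nodes)
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            shared = membership[u] & membership[v]
            p = spec.p_in if shared else spec.p_out
            if rng.random() < p:
                net.add_edge(u, v)

    # re-anchor planted overlap nodes that drew too few intra-block edges
    for node in sorted(spec.overlap_assignments):
        for b in sorted(spec.overlap_assignments[node]):
            others = sorted(blocks[b] - {node})
            while sum(1 for u in others if net.has_edge(node, u)) < 2:
                for u in others:
                    if rng.random() < spec.p_in:
                        net.add_edge(node, u)

    truth = Cover()
    for members in blocks:
        truth.add_community(sorted(members))
    return net, truth


def karate_fixture() -> nx.Graph:
    """The bundled Zachary karate club network: 34 nodes, 78 edges, ids "1".."34"."""
    text = (
        resources.files("overcover")
        .joinpath("data/karate_club.edges")
        .read_text(encoding="utf-8")
    )
    return read_edge_list(text.splitlines())
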