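"""Stage 1: raw community detection and redistribution of unallocated nodes.

The detector grows one community at a time from a randomly chosen unvisited
root.  The root's *core* is the root plus those unlocated neighbors that
close a triangle with it — triangles being the smallest cohesive unit a
community can be built from.  Expansion then proceeds layer by layer: the
frontier is every unlocated neighbor of the previously joined layer, each
frontier node is marked visited and admitted if it passes one of the join
conditions, and expansion stops when a layer admits nobody (or the layer
bound is hit).  Because the vast majority of nodes belong to exactly one
community, the visited/located flags prune nearly all repeat visits: a node
is only ever re-examined if an earlier community could not pin it down.

Join conditions, tried in priority order against the candidate community:

1. joining strictly raises the community's weighted modularity;
2. joining raises internal density while leaving modularity stable
   (|dQ| <= stability_eps);
3. the node's links into the community exceed a third of the community size;
4. the community's modularity after joining clears the quality floor
   (q_threshold) and the move is stable.

Condition 4 is an expansion-stage device only; redistribution and the later
correction pass test conditions 1-3.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .core_graph import Cover, NodeState
from .membership import belonging_factor
from .quality import CommunityModel, QualityParams, weighted_modularity

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "seed_core",
    "node_join_test",
    "group_join_test",
    "find_raw_communities",
    "set_located_flags",
    "redistribute_unallocated",
]

#: Conditions used outside raw expansion (redistribution, correction).
BASE_CONDITIONS: tuple[int, ...] = (1, 2, 3)
ALL_CONDITIONS: tuple[int, ...] = (1, 2, 3, 4)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds steering detection.

    link_frac
        Join condition 3 admits a node whose links into the community exceed
        ``link_frac * n_C``.
    locate_belonging / locate_overlap_edge_ratio
        A node is *located* (pruned from all further examination) when its
        best belonging factor reaches 3/4 and fewer than 1/4 of its incident
        edges lead to foreign communities.  The deliberately strict pair
        keeps every plausible overlap node available to the correction pass.
    correction_keep_factor
        During correction, a membership whose belonging factor reaches this
        bound is kept outright; only weaker memberships face the
        removal-gain check.  Defaults to the same 1/3 rate as the join
        condition: a node retains any community it would still qualify to
        join.
    min_core_size
        Smallest triangle core that seeds a community.
    min_output_size
        Communities smaller than this at finalization are dissolved back to
        the unallocated pool.
    max_layers
        Expansion depth bound (small-world diameter argument).
    """

    quality: QualityParams = field(default_factory=QualityParams)
    link_frac: float = 1.0 / 3.0
    locate_belonging: float = 0.75
    locate_overlap_edge_ratio: float = 0.25
    correction_keep_factor: float = 1.0 / 3.0
    min_core_size: int = 3
    min_output_size: int = 5
    max_layers: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("link_frac", "locate_belonging", "locate_overlap_edge_ratio"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.min_core_size > self.min_output_size:
            logger.warning(
                "min_core_size %d exceeds min_output_size %d",
                self.min_core_size,
                self.min_output_size,
            )


def seed_core(
    net: nx.Graph,
    root: str,
    states: dict[str, NodeState],
    params: DetectionParams,
) -> CommunityModel | None:
    """Form the triangle core of a new community around ``root``.

    The core is the root plus every unlocated neighbor that shares at least
    one other unlocated neighbor with the root (i.e. closes a triangle inside
    the candidate set).  If the core reaches ``min_core_size`` all core nodes
    are marked visited and the community model is returned; otherwise only
    the root is marked visited and ``None`` is returned.
    """
    if states[root].is_visited:
        raise ValueError(f"root {root!r} is already visited")
    candidates = {u for u in net[root] if not states[u].is_located}
    core = {root}
    for u in sorted(candidates):
        if any(w != u and net.has_edge(u, w) for w in candidates):
            core.add(u)
    if len(core) < params.min_core_size:
        states[root].is_visited = True
        return None
    for v in core:
        states[v].is_visited = True
    return CommunityModel.from_members(core, net)


def _join_conditions(
    links: int,
    degree: int,
    model: CommunityModel,
    trial: CommunityModel,
    params: DetectionParams,
    conditions: Sequence[int],
) -> int | None:
    q = params.quality
    q_before = weighted_modularity(model, q)
    q_after = weighted_modularity(trial, q)
    dq = q_after - q_before
    stable = abs(dq) <= q.stability_eps
    if 1 in conditions and dq > 0:
        return 1
    if 2 in conditions and stable:
        d_before = 2.0 * model.k_in / (model.n_c * (model.n_c - 1))
        d_after = 2.0 * trial.k_in / (trial.n_c * (trial.n_c - 1))
        if d_after > d_before:
            return 2
    if 3 in conditions and links > params.link_frac * model.n_c:
        return 3
    if 4 in conditions and q_after >= q.q_threshold and stable:
        return 4
    return None


def node_join_test(
    node: str,
    model: CommunityModel,
    net: nx.Graph,
    params: DetectionParams,
    conditions: Sequence[int] = ALL_CONDITIONS,
) -> int | None:
    """Index (1..4) of the first join condition ``node`` satisfies, else None."""
    if node in model.members:
        raise ValueError(f"node {node!r} already in community")
    links = model.member_links(node, net)
    trial = model.copy().add_node(node, net)
    return _join_conditions(links, net.degree(node), model, trial, params, conditions)


def group_join_test(
    nodes: Iterable[str],
    model: CommunityModel,
    net: nx.Graph,
    params: DetectionParams,
    conditions: Sequence[int] = BASE_CONDITIONS,
) -> int | None:
    """Join test for a node group admitted as one block (union join)."""
    group = set(nodes)
    links = sum(model.member_links(v, net) for v in group)
    degree = sum(net.degree(v) for v in group)
    trial = model.copy()
    for v in sorted(group):
        trial.add_node(v, net)
    return _join_conditions(links, degree, model, trial, params, conditions)


def set_located_flags(
    cover: Cover,
    net: nx.Graph,
    states: dict[str, NodeState],
    params: DetectionParams,
    nodes: Iterable[str] | None = None,
) -> dict[str, NodeState]:
    """Confirm the located flag for covered nodes.

    A node is located when its maximum belonging factor reaches
    ``locate_belonging`` *and* the fraction of its incident edges that are
    overlapping edges stays below ``locate_overlap_edge_ratio``.  An
    overlapping edge is a connection to an overlap node (a neighbor held by
    two or more communities), so a node sitting next to a shared region is
    deliberately kept available to the correction pass.  Flags are only ever
    raised here, never cleared: nodes placed later by redistribution keep
    ``is_located=False`` so the correction pass will examine them.
    """
    targets = sorted(nodes) if nodes is not None else sorted(cover.covered_nodes())
    for v in targets:
        cids = cover.communities_of(v)
        if not cids or net.degree(v) == 0:
            continue
        best = max(belonging_factor(v, cover.communities[c], net) for c in cids)
        if best < params.locate_belonging:
            continue
        overlapping = sum(1 for u in net[v] if cover.membership_number(u) >= 2)
        if overlapping / net.degree(v) < params.locate_overlap_edge_ratio:
            states[v].locate()
    return states


def find_raw_communities(
    net: nx.Graph,
    params: DetectionParams | None = None,
    roots: Sequence[str] | None = None,
    visit_counter: dict[str, int] | None = None,
    condition_tally: dict[int, int] | None = None,
) -> tuple[Cover, dict[str, NodeState]]:
    """Run raw detection until every node has been visited.

    ``roots`` optionally fixes the root sequence (unvisited entries are used
    in order); once exhausted, roots are drawn uniformly from the unvisited
    nodes under the seeded RNG.  ``visit_counter`` and ``condition_tally``,
    when supplied, are filled with per-node visit counts and with how often
    each join condition fired.
    """
    params = params or DetectionParams()
    states = {v: NodeState() for v in net.nodes}
    cover = Cover()
    rng = random.Random(params.seed)
    root_queue = list(roots or ())

    def record_visit(v: str) -> None:
        if visit_counter is not None:
            visit_counter[v] = visit_counter.get(v, 0) + 1

    def next_root() -> str | None:
        while root_queue:
            candidate = root_queue.pop(0)
            if not states[candidate].is_visited:
                return candidate
        unvisited = sorted(v for v in net.nodes if not states[v].is_visited)
        if not unvisited:
            return None
        return rng.choice(unvisited)

    while True:
        root = next_root()
        if root is None:
            break
        model = seed_core(net, root, states, params)
        record_visit(root)
        if model is None:
            continue
        for v in model.members:
            if v != root:
                record_visit(v)
        layer = sorted(model.members)
        depth = 0
        while True:
            frontier = sorted(
                {
                    u
                    for v in layer
                    for u in net[v]
                    if u not in model.members and not states[u].is_located
                }
            )
            if not frontier:
                break
            if depth >= params.max_layers:
                logger.info(
                    "community rooted at %r hit the %d-layer expansion bound",
                    root,
                    params.max_layers,
                )
                break
            depth += 1
            joined: list[str] = []
            for u in frontier:
                states[u].is_visited = True
                record_visit(u)
                fired = node_join_test(u, model, net, params)
                if fired is not None:
                    if condition_tally is not None:
                        condition_tally[fired] = condition_tally.get(fired, 0) + 1
                    model.add_node(u, net)
                    joined.append(u)
            if not joined:
                break
            layer = joined
        if model.n_c >= params.min_output_size:
            cid = cover.add_community(sorted(model.members))
            set_located_flags(cover, net, states, params, nodes=model.members)
            logger.info(
                "output community %s with %d nodes after %d layers", cid, model.n_c, depth
            )
        else:
            logger.info(
                "dissolving undersized community around %r (%d nodes)", root, model.n_c
            )
    return cover, states


# ---------------------------------------------------------------------------
# redistribution
# ---------------------------------------------------------------------------


def _candidate_communities(
    group: set[str], cover: Cover, net: nx.Graph, params: DetectionParams
) -> list[tuple[str, int, float]]:
    """Adjacent communities ranked by (links into group, resulting modularity)."""
    links: dict[str, int] = {}
    for v in group:
        for u in net[v]:
            for cid in cover.node_index.get(u, ()):
                links[cid] = links.get(cid, 0) + 1
    ranked = []
    for cid, n_links in links.items():
        model = CommunityModel.from_members(cover.communities[cid], net)
        trial = model.copy()
        for v in sorted(group):
            if v not in trial.members:
                trial.add_node(v, net)
        q_after = weighted_modularity(trial, params.quality) if trial.k_in else 0.0
        ranked.append((cid, n_links, q_after))
    ranked.sort(key=lambda item: (-item[1], -item[2], item[0]))
    return ranked


def _allocate_group(
    group: set[str],
    cover: Cover,
    net: nx.Graph,
    params: DetectionParams,
) -> str | None:
    """Join ``group`` (possibly a single node) to its best adjacent community.

    Candidates are tried in order of connection strength; the first one
    passing the join test wins.  If none passes, the group is force-joined to
    the top-ranked candidate so the cover stays total.  Returns the chosen
    community id, or None when no adjacent community exists.
    """
    ranked = _candidate_communities(group, cover, net, params)
    if not ranked:
        return None
    chosen = None
    for cid, _links, _q in ranked:
        model = CommunityModel.from_members(cover.communities[cid], net)
        ok = (
            group_join_test(group, model, net, params)
            if len(group) > 1
            else node_join_test(next(iter(group)), model, net, params, BASE_CONDITIONS)
        )
        if ok is not None:
            chosen = cid
            break
    if chosen is None:
        chosen = ranked[0][0]
        logger.info(
            "force-joining %s to %s (no join condition met)", sorted(group), chosen
        )
    for v in sorted(group):
        cover.add_member(chosen, v)
    return chosen


def _triangle_nodes(sub: nx.Graph) -> set[str]:
    tri = set()
    for u, v in sub.edges():
        if any(True for _ in nx.common_neighbors(sub, u, v)):
            tri.update({u, v} | set(nx.common_neighbors(sub, u, v)))
    return tri


def redistribute_unallocated(
    net: nx.Graph,
    cover: Cover,
    states: dict[str, NodeState],
    params: DetectionParams,
) -> tuple[Cover, dict[str, NodeState]]:
    """Place every visited-but-unallocated node, or mark it isolated.

    Unallocated nodes are processed as connected components (largest first).
    Inside a component, nodes forming triangles are too interdependent for
    any single one to pass a join test alone: a triangle-connected group
    large enough to stand on its own (``min_output_size``) is installed as an
    independent community, a smaller one is admitted to a neighboring
    community as one block (union join).  The remaining nodes that touch the
    cover directly are placed one by one; nodes that reach the cover only
    through other unallocated nodes are the tail of a chain and are marked
    isolated.
    """
    unallocated = sorted(
        v
        for v in net.nodes
        if v not in cover.node_index and not states[v].is_isolated
    )
    if not unallocated:
        return cover, states
    sub = net.subgraph(unallocated)
    components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    for comp in components:
        comp = set(comp)
        tri = _triangle_nodes(sub.subgraph(comp))
        for block in sorted(
            nx.connected_components(sub.subgraph(tri) if tri else nx.Graph()),
            key=min,
        ):
            block = set(block)
            if len(block) >= params.min_output_size:
                # able to form one or more independent clusters of its own:
                # re-run raw detection on the induced subgraph so that a
                # group spanning several dense regions is split, not lumped
                sub_net = nx.Graph(net.subgraph(block))
                sub_cover, _ = find_raw_communities(sub_net, params)
                placed: set[str] = set()
                for members in sub_cover.communities.values():
                    cid = cover.add_community(sorted(members))
                    placed |= set(members)
                    # a group standing alone is a raw detection in its own
                    # right, so its located flags are confirmed as usual
                    set_located_flags(cover, net, states, params, nodes=members)
                    logger.info(
                        "unallocated group %s installed as community %s",
                        sorted(members),
                        cid,
                    )
                if not placed:
                    cid = cover.add_community(sorted(block))
                    set_located_flags(cover, net, states, params, nodes=block)
                    logger.info(
                        "unallocated group %s installed whole as community %s",
                        sorted(block),
                        cid,
                    )
            elif _allocate_group(block, cover, net, params) is None:
                for v in sorted(block):
                    states[v].is_isolated = True
                    cover.isolated.add(v)
        remaining = sorted(comp - cover.covered_nodes() - cover.isolated)
        # chain rule: only nodes touching the cover *now* are allocated;
        # deeper chain nodes would reach it only through each other.
        anchored = {
            v
            for v in remaining
            if any(u in cover.node_index for u in net[v])
        }
        for v in remaining:
            if v in anchored:
                if _allocate_group({v}, cover, net, params) is None:
                    states[v].is_isolated = True
                    cover.isolated.add(v)
            else:
                states[v].is_isolated = True
                cover.isolated.add(v)
    return cover, states
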