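"""Stage 2: error detection and correction for specific nodes.

Specific nodes are those still unlocated after stage 1 — overlap candidates,
late joiners that lacked neighborhood information when first examined, and
everything redistribution placed.  Each is audited with a seven-step
procedure: try to join each adjacent community (conditions 1-3), fall back
to an even-split join when the belonging factors over the adjacent
communities are averagely distributed, and finally re-check each current
membership — a weakly attached membership whose removal raises the
community's weighted modularity is dropped.

Because a freshly corrected overlap node changes its neighbors' belonging
factors, the procedure is re-run on mutually linked overlap nodes until a
pass changes nothing.  Run over *all* nodes instead of the specific set, the
same procedure audits a cover produced by any other algorithm: a cover is
steady exactly when no membership changes.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import networkx as nx

from .core_graph import Cover, NodeState, ValidationError
from .detect import BASE_CONDITIONS, DetectionParams, node_join_test
from .membership import belonging_factor, is_average_distribution
from .quality import CommunityModel, removal_delta_modularity

logger = logging.getLogger(__name__)

__all__ = [
    "Action",
    "CorrectionReport",
    "find_specific_nodes",
    "correct_node",
    "run_correction",
    "recorrect_mutual_overlaps",
    "audit_cover",
]


class Action(enum.Enum):
    JOINED = "joined"
    REMOVED = "removed"
    EQUAL_SPLIT = "equal_split"
    UNCHANGED = "unchanged"


@dataclass
class CorrectionReport:
    """What a correction (or audit) run examined and changed."""

    specific_nodes: list[str] = field(default_factory=list)
    changes: list[tuple[str, Action, tuple[str, ...]]] = field(default_factory=list)
    passes: int = 0
    stable: bool = True

    def changed_nodes(self) -> set[str]:
        return {node for node, _, _ in self.changes}


def find_specific_nodes(states: dict[str, NodeState]) -> list[str]:
    """Unlocated, non-isolated nodes, lexicographically ordered."""
    return sorted(
        v for v, s in states.items() if not s.is_located and not s.is_isolated
    )


def _model(cover: Cover, cid: str, net: nx.Graph) -> CommunityModel:
    return CommunityModel.from_members(cover.communities[cid], net)


def correct_node(
    node: str,
    cover: Cover,
    net: nx.Graph,
    params: DetectionParams,
) -> tuple[Action, tuple[str, ...]]:
    """Audit one node in place; returns the action taken and the communities touched.

    Steps: (1) list adjacent communities (those holding a neighbor but not
    the node); (2) join each that the node passes conditions 1-3 for; (3) if
    at least two adjacent communities remain and the belonging factors over
    the adjacent communities are averagely distributed, join them all (equal
    split); (5) with a single membership, stop; (6/7) for each membership
    whose belonging factor falls short of the retention threshold, drop it if
    removal raises that community's weighted modularity.
    """
    current = cover.communities_of(node)
    neighbor_comms: set[str] = set()
    for u in net[node]:
        neighbor_comms |= cover.node_index.get(u, set())
    adjacent = sorted(
        neighbor_comms - current,
        key=lambda cid: (-belonging_factor(node, cover.communities[cid], net), cid),
    )

    joined: list[str] = []
    if adjacent:
        for cid in adjacent:
            model = _model(cover, cid, net)
            if model.n_c < 2 or model.k_in < 1:
                continue
            if node_join_test(node, model, net, params, BASE_CONDITIONS) is not None:
                cover.add_member(cid, node)
                joined.append(cid)
        untried = [cid for cid in adjacent if cid not in joined]
        if len(adjacent) >= 2 and untried:
            factors = [
                belonging_factor(node, cover.communities[cid], net) for cid in adjacent
            ]
            if is_average_distribution(factors):
                for cid in untried:
                    cover.add_member(cid, node)
                return Action.EQUAL_SPLIT, tuple(adjacent)
    elif not current:
        logger.info("node %r has neither membership nor adjacent community", node)
        return Action.UNCHANGED, ()

    belonging = sorted(cover.communities_of(node))
    if len(belonging) == 1:
        return (Action.JOINED, tuple(joined)) if joined else (Action.UNCHANGED, ())

    removed: list[str] = []
    for cid in belonging:
        if cover.membership_number(node) <= 1:
            break
        factor = belonging_factor(node, cover.communities[cid], net)
        if factor >= params.correction_keep_factor:
            continue
        if removal_delta_modularity(_model(cover, cid, net), node, net, params.quality) > 0:
            cover.remove_member(cid, node)
            removed.append(cid)
    if removed:
        return Action.REMOVED, tuple(removed)
    return (Action.JOINED, tuple(joined)) if joined else (Action.UNCHANGED, ())


def _cover_fingerprint(cover: Cover) -> int:
    return hash(
        frozenset((cid, frozenset(members)) for cid, members in cover.communities.items())
    )


def recorrect_mutual_overlaps(
    cover: Cover,
    net: nx.Graph,
    params: DetectionParams,
    report: CorrectionReport | None = None,
) -> CorrectionReport:
    """Re-run correction on mutually linked overlap nodes until stable.

    Interacting overlaps can flip one another's belonging factors, so passes
    repeat until one changes nothing.  A revisited cover state (oscillation)
    or exceeding |V| passes aborts with ``stable=False``.
    """
    report = report or CorrectionReport()
    seen = {_cover_fingerprint(cover)}
    for _ in range(net.number_of_nodes()):
        overlaps = cover.overlap_nodes()
        mutual = sorted(v for v in overlaps if any(u in overlaps for u in net[v]))
        if not mutual:
            report.stable = True
            return report
        changed = False
        for node in mutual:
            action, cids = correct_node(node, cover, net, params)
            if action is not Action.UNCHANGED and cids:
                report.changes.append((node, action, cids))
                changed = True
        report.passes += 1
        if not changed:
            report.stable = True
            return report
        fingerprint = _cover_fingerprint(cover)
        if fingerprint in seen:
            logger.warning("correction oscillates; aborting")
            report.stable = False
            return report
        seen.add(fingerprint)
    report.stable = False
    return report


def run_correction(
    cover: Cover,
    net: nx.Graph,
    states: dict[str, NodeState],
    params: DetectionParams,
) -> CorrectionReport:
    """One correction pass over the specific nodes, then the mutual-overlap re-run."""
    report = CorrectionReport(specific_nodes=find_specific_nodes(states))
    for node in report.specific_nodes:
        action, cids = correct_node(node, cover, net, params)
        if action is not Action.UNCHANGED and cids:
            report.changes.append((node, action, cids))
    report.passes = 1
    return recorrect_mutual_overlaps(cover, net, params, report)


def audit_cover(
    cover: Cover,
    net: nx.Graph,
    params: DetectionParams | None = None,
) -> CorrectionReport:
    """Validity check of an externally produced cover.

    Every node is treated as specific and audited against a working copy;
    the cover is steady and accurate exactly when no membership changes.
    The input cover is left untouched.
    """
    params = params or DetectionParams()
    cover.validate(net)
    uncovered = set(net.nodes) - cover.covered_nodes() - cover.isolated
    if uncovered:
        raise ValidationError(
            f"cover leaves nodes unassigned: {sorted(uncovered)[:10]}"
        )
    work = cover.copy()
    report = CorrectionReport(specific_nodes=sorted(net.nodes))
    for node in report.specific_nodes:
        if node in work.isolated:
            continue
        action, cids = correct_node(node, work, net, params)
        if action is not Action.UNCHANGED and cids:
            report.changes.append((node, action, cids))
    report.passes = 1
    report.stable = not report.changes
    return report
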