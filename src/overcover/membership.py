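"""Belonging factors, membership vectors and the overlapping-node criteria.

The belonging factor of node *i* in community *C* is the fraction of *i*'s
neighbors that are members of *C*.  A neighbor shared by several communities
counts toward each of them, which is why the factors of an overlap node can
sum to more than 1.0 (e.g. a node with vector [0.3, 0.4, 0.4] sums to 1.1):
overlap edges are internal to every community they touch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import networkx as nx

from .core_graph import Cover
from .quality import (
    CommunityModel,
    QualityParams,
    community_density,
    delta_modularity,
    weighted_modularity,
)

__all__ = [
    "MembershipVector",
    "OverlapCondition",
    "belonging_factor",
    "membership_vector",
    "is_average_distribution",
    "overlap_condition",
]

#: Whole-graph density at or above which a network counts as "dense" for the
#: internal-strengthening criterion (the karate club sits at 0.139, the
#: protein reaction network at 0.290).
DENSE_NETWORK_THRESHOLD = 0.20


@dataclass(frozen=True)
class MembershipVector:
    """A node's belonging factors across the communities containing it."""

    node: str
    entries: tuple[tuple[str, float], ...]

    @property
    def c(self) -> int:
        """Membership number: how many communities the node belongs to."""
        return len(self.entries)

    @property
    def factors(self) -> tuple[float, ...]:
        return tuple(f for _, f in self.entries)

    @property
    def total(self) -> float:
        return sum(self.factors)


class OverlapCondition(enum.Enum):
    """Which overlap criterion a node satisfies, in priority order."""

    MODULARITY_ADDITION = 1
    INTERNAL_STRENGTHEN = 2
    AVERAGE_DISTRIBUTION = 3
    NONE = 0


def belonging_factor(node: str, community: set[str], net: nx.Graph) -> float:
    """Fraction of ``node``'s neighbors that are members of ``community``."""
    degree = net.degree(node)
    if degree == 0:
        raise ValueError(f"node {node!r} has degree 0")
    inside = sum(1 for u in net[node] if u in community)
    return inside / degree


def membership_vector(node: str, cover: Cover, net: nx.Graph) -> MembershipVector:
    """Belonging factors of ``node`` over exactly the communities containing it."""
    cids = cover.communities_of(node)
    if not cids:
        raise ValueError(f"node {node!r} is not covered by any community")
    entries = tuple(
        (cid, belonging_factor(node, cover.communities[cid], net))
        for cid in sorted(cids)
    )
    return MembershipVector(node=node, entries=entries)


def is_average_distribution(factors) -> bool:
    """True iff the factors deviate from the uniform vector by at most 1/(2c).

    The test is Σ_c |a_c − 1/c| ≤ 1/(2c) with c = len(factors); the dynamic
    threshold tightens as the membership number grows.  Boundary cases are
    inclusive: [0.3, 0.4, 0.4] deviates by exactly 1/6 and passes.
    """
    if isinstance(factors, MembershipVector):
        factors = factors.factors
    c = len(factors)
    if c < 2:
        raise ValueError("average-distribution test needs membership number >= 2")
    deviation = sum(abs(a - 1.0 / c) for a in factors)
    # tiny epsilon absorbs float noise at the inclusive boundary (e.g. 1/6)
    return deviation <= 1.0 / (2 * c) + 1e-12


def overlap_condition(
    node: str,
    cover: Cover,
    net: nx.Graph,
    params: QualityParams | None = None,
    dense_threshold: float = DENSE_NETWORK_THRESHOLD,
) -> OverlapCondition:
    """Classify which overlap criterion ``node`` meets, highest priority first.

    1. *Modularity addition*: the node's presence raises the weighted
       modularity of every community it belongs to.
    2. *Internal strengthening*: re-adding the node raises internal density
       in each community while leaving modularity stable (sparse networks),
       or — in dense networks — more than a third of the node's neighbors
       sit in each community.
    3. *Average distribution*: the belonging factors are spread evenly
       (within the dynamic threshold) across the communities.
    """
    params = params or QualityParams()
    cids = sorted(cover.communities_of(node))
    if len(cids) < 2:
        return OverlapCondition.NONE

    vec = membership_vector(node, cover, net)
    models = {
        cid: CommunityModel.from_members(cover.communities[cid] - {node}, net)
        for cid in cids
    }

    def addable(model: CommunityModel) -> bool:
        return model.n_c >= 2 and model.k_in >= 1

    if all(
        addable(m) and delta_modularity(m, node, net, params) > 0
        for m in models.values()
    ):
        return OverlapCondition.MODULARITY_ADDITION

    dense = nx.density(net) >= dense_threshold
    if dense:
        if all(f > 1.0 / 3.0 for f in vec.factors):
            return OverlapCondition.INTERNAL_STRENGTHEN
    else:
        def strengthens(model: CommunityModel) -> bool:
            if not addable(model):
                return False
            dq = delta_modularity(model, node, net, params)
            d_before = community_density(model)
            d_after = community_density(model.copy().add_node(node, net))
            return d_after > d_before and abs(dq) <= params.stability_eps

        if all(strengthens(m) for m in models.values()):
            return OverlapCondition.INTERNAL_STRENGTHEN

    if is_average_distribution(vec):
        return OverlapCondition.AVERAGE_DISTRIBUTION
    return OverlapCondition.NONE
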