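"""Community quality functions: density, fitness, and weighted modularity.

The weighted modularity of a community :math:`C` blends two classical local
scores with an allocation parameter :math:`\\beta`:

.. math::

    Q_C = \\beta \\frac{2 k^{in}_C}{n_C (n_C - 1)}
        + (1-\\beta) \\frac{2 k^{in}_C}{2 k^{in}_C + k^{out}_C}

where :math:`n_C` is the member count, :math:`k^{in}_C` the number of edges
with both ends inside the community and :math:`k^{out}_C` the number with
exactly one end inside.  The first term is the internal edge density, the
second the cohesion (the classical fitness at :math:`\\alpha = 1`).  Unlike
fitness alone, the blend separates an isolated clique (density 1) from an
isolated ring (density :math:`2/(n-1)`), which matters in networks — protein
interaction modules in particular — where the internal wiring pattern, not
just the boundary, carries meaning.

All counts live in an incrementally updatable :class:`CommunityModel` so that
candidate evaluations during detection cost O(degree) instead of a recount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "QualityParams",
    "CommunityModel",
    "community_density",
    "fitness",
    "weighted_modularity",
    "cover_modularity",
    "delta_modularity",
    "delta_modularity_set",
    "removal_delta_modularity",
]


@dataclass(frozen=True)
class QualityParams:
    """Tunable quality parameters.

    beta
        Weight of the density term, in (0, 0.5]; the default 0.2 follows the
        Pareto 20/80 split between density and cohesion.
    alpha
        Fitness size regulator (only used by :func:`fitness`).
    q_threshold
        Modularity floor used by the threshold join condition; 0.750 is the
        observed minimum community modularity at beta = 0.2 on networks with
        well-known structure.
    stability_eps
        |dQ| bound below which a candidate move counts as "stable"
        (the smoothness tolerance).
    """

    beta: float = 0.2
    alpha: float = 1.0
    q_threshold: float = 0.750
    stability_eps: float = 0.015

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 0.5:
            raise ValueError(f"beta must lie in (0, 0.5], got {self.beta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass
class CommunityModel:
    """One community's member set with incrementally maintained edge counts.

    ``k_in`` counts edges with both ends in ``members``; ``k_out`` those with
    exactly one end inside.  After any sequence of :meth:`add_node` /
    :meth:`remove_node` calls the counts equal a from-scratch recount.
    """

    members: set[str] = field(default_factory=set)
    k_in: int = 0
    k_out: int = 0

    @property
    def n_c(self) -> int:
        return len(self.members)

    @classmethod
    def from_members(cls, members: Iterable[str], net: nx.Graph) -> "CommunityModel":
        model = cls(members=set(members))
        k_in = k_out = 0
        for v in model.members:
            for u in net[v]:
                if u in model.members:
                    k_in += 1
                else:
                    k_out += 1
        model.k_in = k_in // 2
        model.k_out = k_out
        return model

    def member_links(self, node: str, net: nx.Graph) -> int:
        """Number of ``node``'s neighbors inside the community."""
        return sum(1 for u in net[node] if u in self.members)

    def add_node(self, node: str, net: nx.Graph) -> "CommunityModel":
        if node in self.members:
            raise ValueError(f"node {node!r} already in community")
        inside = self.member_links(node, net)
        self.members.add(node)
        self.k_in += inside
        self.k_out += net.degree(node) - 2 * inside
        return self

    def remove_node(self, node: str, net: nx.Graph) -> "CommunityModel":
        if node not in self.members:
            raise ValueError(f"node {node!r} not in community")
        self.members.remove(node)
        inside = self.member_links(node, net)
        self.k_in -= inside
        self.k_out -= net.degree(node) - 2 * inside
        return self

    def copy(self) -> "CommunityModel":
        return CommunityModel(members=set(self.members), k_in=self.k_in, k_out=self.k_out)


def community_density(model: CommunityModel) -> float:
    """Internal edge density ``2 k_in / (n_C (n_C - 1))``."""
    if model.n_c < 2:
        raise ValueError("community density needs at least two members")
    return 2.0 * model.k_in / (model.n_c * (model.n_c - 1))


def fitness(model: CommunityModel, alpha: float = 1.0) -> float:
    """Local fitness ``2 k_in / (2 k_in + k_out)**alpha``."""
    total = 2 * model.k_in + model.k_out
    if total <= 0:
        raise ValueError("fitness undefined for a community without edges")
    return 2.0 * model.k_in / total**alpha

def weighted_modularity(model: CommunityModel, params: QualityParams) -> float:
    """Density+cohesion weighted modularity of a single community.

    Equals 1.0 exactly when the community is an isolated clique.
    """
    if model.n_c < 2:
        raise ValueError("weighted modularity needs at least two members")
    if model.k_in < 1:
        raise ValueError("weighted modularity needs at least one internal edge")
    density = 2.0 * model.k_in / (model.n_c * (model.n_c - 1))
    cohesion = 2.0 * model.k_in / (2 * model.k_in + model.k_out)
    return params.beta * density + (1.0 - params.beta) * cohesion


def cover_modularity(cover, net: nx.Graph, params: QualityParams) -> float:
    """Whole-network modularity: arithmetic mean over the cover's communities."""
    if not len(cover):
        raise ValueError("cover has no communities")
    scores = [
        weighted_modularity(CommunityModel.from_members(members, net), params)
        for members in cover.communities.values()
    ]
    return sum(scores) / len(scores)


def delta_modularity(
    model: CommunityModel, node: str, net: nx.Graph, params: QualityParams
) -> float:
    """Change in the community's weighted modularity if ``node`` joined.

    The input model is not mutated.
    """
    before = weighted_modularity(model, params)
    after = weighted_modularity(model.copy().add_node(node, net), params)
    return after - before


def delta_modularity_set(
    model: CommunityModel, nodes: Iterable[str], net: nx.Graph, params: QualityParams
) -> float:
    """Change in modularity if a whole node group joined at once."""
    before = weighted_modularity(model, params)
    trial = model.copy()
    for node in nodes:
        trial.add_node(node, net)
    return weighted_modularity(trial, params) - before


def removal_delta_modularity(
    model: CommunityModel, node: str, net: nx.Graph, params: QualityParams
) -> float:
    """Change in modularity if ``node`` left the community (not mutated)."""
    before = weighted_modularity(model, params)
    trial = model.copy().remove_node(node, net)
    if trial.n_c < 2 or trial.k_in < 1:
        return float("-inf")
    return weighted_modularity(trial, params) - before
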