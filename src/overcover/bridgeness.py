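"""Bridgeness scores quantifying how an overlap node is shared.

Original bridgeness measures only how close a node's membership vector
[a_1, ..., a_c] is to the uniform reference [1/c, ..., 1/c]:

    b_i = 1 - sqrt( c/(c-1) * sum_r (a_r - 1/c)^2 )

It is 0 for a node in a single community and 1.0 when the communities share
the node exactly evenly — regardless of how many communities there are or how
well-connected the node is, which makes equally-shared low-degree nodes look
as important as hubs.

The improved variant centres the deviation on the node's *actual* mean factor
(belonging factors of an overlap node sum to >= 1, so 1/c is not their mean)
and charges penalty terms that shrink with the membership number c and the
degree k:

    b_i = 1 - sqrt( c/(c-1) * sum_r (a_r - a_bar)^2 + 1/c^2 + 1/k )

so among equally-even nodes the higher-degree, higher-membership one scores
higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .core_graph import Cover
from .membership import membership_vector

__all__ = [
    "BridgenessRecord",
    "original_bridgeness",
    "improved_bridgeness",
    "bridgeness_table",
]


@dataclass(frozen=True)
class BridgenessRecord:
    """One table row for an overlap node."""

    node: str
    degree: int
    c: int
    factors: tuple[float, ...]
    b_original: float
    b_improved: float

    @property
    def a_bar(self) -> float:
        return sum(self.factors) / len(self.factors)


def original_bridgeness(factors: Sequence[float]) -> float:
    """Deviation of the membership vector from the uniform reference.

    Returns 0.0 for a single-community node.
    """
    c = len(factors)
    if c == 0:
        raise ValueError("empty membership vector")
    if c == 1:
        return 0.0
    spread = sum((a - 1.0 / c) ** 2 for a in factors)
    return 1.0 - math.sqrt(c / (c - 1) * spread)


def improved_bridgeness(factors: Sequence[float], degree: int) -> float:
    """Degree- and membership-aware bridgeness; always < 1 for finite degree."""
    c = len(factors)
    if c < 2:
        raise ValueError("improved bridgeness needs membership number >= 2")
    if degree < c:
        raise ValueError(
            f"membership number {c} cannot exceed degree {degree}"
        )
    a_bar = sum(factors) / c
    spread = sum((a - a_bar) ** 2 for a in factors)
    return 1.0 - math.sqrt(c / (c - 1) * spread + 1.0 / c**2 + 1.0 / degree)


def bridgeness_table(cover: Cover, net: nx.Graph) -> list[BridgenessRecord]:
    """One record per overlap node (membership number >= 2), sorted by node id."""
    records = []
    for node in sorted(cover.overlap_nodes()):
        vec = membership_vector(node, cover, net)
        records.append(
            BridgenessRecord(
                node=node,
                degree=net.degree(node),
                c=vec.c,
                factors=vec.factors,
                b_original=original_bridgeness(vec.factors),
                b_improved=improved_bridgeness(vec.factors, net.degree(node)),
            )
        )
    return records
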