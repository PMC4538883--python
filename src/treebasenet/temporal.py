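"""Weak and strong temporal orderings of tree-based networks.

A time map t on the vertices of a network with support tree T' is a *strong
temporal ordering* when t strictly increases along every support-tree arc and
is constant across every linking arc (both donors of a reticulate event are
contemporaries).  Relaxing the equality to t(u) <= t(v) gives a *weak*
temporal ordering, which allows unsampled or extinct intermediaries.  Every
acyclic network has a weak temporal ordering (any topological numbering
works), whereas a strong ordering may fail to exist for every support tree.

The strong-ordering decision merges the endpoints of each linking arc into
equivalence classes; a strong ordering exists for the given support tree iff
the quotient graph of support-tree arcs is acyclic, in which case each class
is timed by its longest-path level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import networkx as nx

from .errors import InvalidNetworkError
from .network_core import PhyloNetwork, require_valid
from .treebased import (
    SupportTree,
    TruncatableList,
    admissibility_violations,
    enumerate_support_trees,
)

YES = "yes"
NO = "no"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class TemporalOrdering:
    """Vertex times; strict along support-tree arcs, and across linking arcs
    equal (strong) or non-decreasing (weak)."""

    times: Dict[str, float]
    kind: str  # weak | strong
    support: Optional[SupportTree] = None


@dataclass(frozen=True)
class StrongOrderingResult:
    status: str  # yes | no | unknown
    ordering: Optional[TemporalOrdering] = None
    support: Optional[SupportTree] = None
    reason: Optional[str] = None


def weak_temporal_ordering(net: PhyloNetwork) -> TemporalOrdering:
    """A topological numbering: strict on every arc, hence weak relative to
    any support tree.  Errors on cyclic input."""
    if not net.is_acyclic():
        raise InvalidNetworkError("network is cyclic; no weak temporal ordering exists")
    order = list(nx.lexicographical_topological_sort(nx.DiGraph(net.simple_digraph())))
    return TemporalOrdering({v: float(i) for i, v in enumerate(order)}, "weak")


def strong_temporal_ordering(
    net: PhyloNetwork, support: SupportTree
) -> Optional[TemporalOrdering]:
    """Strong ordering relative to ``support``, or ``None`` if none exists."""
    problems = admissibility_violations(net, support.S)
    if problems:
        raise ValueError("support arc set is not admissible: " + "; ".join(problems))
    # Merge linking-arc endpoints (condition: equal times across linking arcs).
    parent = {v: v for v in net.vertices()}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for aid in sorted(support.linking_arcs):
        arc = net.arc(aid)
        ru, rv = find(arc.source), find(arc.target)
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)

    quotient = nx.DiGraph()
    quotient.add_nodes_from({find(v) for v in net.vertices()})
    for aid in sorted(support.S):
        arc = net.arc(aid)
        cu, cv = find(arc.source), find(arc.target)
        if cu == cv:
            return None  # a support arc inside one class forces t(u) < t(u)
        quotient.add_edge(cu, cv)
    if not nx.is_directed_acyclic_graph(quotient):
        return None
    level: Dict[str, int] = {}
    for cls in nx.topological_sort(quotient):
        level[cls] = 1 + max(
            (level[p] for p in quotient.predecessors(cls)), default=-1
        )
    times = {v: float(level[find(v)]) for v in net.vertices()}
    ordering = TemporalOrdering(times, "strong", support)
    _check_ordering(net, ordering)
    return ordering


def _check_ordering(net: PhyloNetwork, ordering: TemporalOrdering) -> None:
    """Verify conditions (i)/(ii) directly; internal consistency guard."""
    assert ordering.support is not None
    times = ordering.times
    for aid in ordering.support.S:
        arc = net.arc(aid)
        assert times[arc.source] < times[arc.target], aid
    for aid in ordering.support.linking_arcs:
        arc = net.arc(aid)
        assert times[arc.source] == times[arc.target], aid


def exists_strong_temporal_ordering(
    net: PhyloNetwork, limit: int = 1024
) -> StrongOrderingResult:
    """Search all support trees (up to ``limit``) for a strong ordering.

    ``no`` with a reason distinguishes the vacuous case (no support tree at
    all, i.e. the network is not tree-based) from exhaustion.
    """
    supports: TruncatableList = enumerate_support_trees(net, limit)
    for support in supports:
        ordering = strong_temporal_ordering(net, support)
        if ordering is not None:
            return StrongOrderingResult(YES, ordering=ordering, support=support)
    if supports.truncated:
        return StrongOrderingResult(UNKNOWN, reason="support-tree enumeration truncated")
    if not supports:
        return StrongOrderingResult(
            NO, reason="network is not tree-based (no support tree exists)"
        )
    return StrongOrderingResult(NO, reason="every support tree admits no strong ordering")
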