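"""Structural screens for tree-basedness: antichains, flows, class predicates.

Two necessary conditions give fast negative screens.  First, the largest
antichain (a vertex set with no directed path between any two members) of a
tree-based network has size exactly |X|, so any network with a larger
antichain cannot be tree-based.  Second, the *antichain-to-leaf property*:
every antichain of non-leaf vertices must admit that many pairwise
arc-disjoint directed paths to the leaf set (equivalently, by Menger, cutting
fewer arcs cannot separate the antichain from X).  The property is necessary
but not sufficient.

Sufficient conditions come from known network classes, all contained in the
tree-based class: tree-child, tree-sibling, reticulation-visible, and the
"every reticulation has two bifurcating parents" condition; conversely a
reticulation whose parents both have out-degree 1 rules tree-basedness out.

Antichains range over ALL vertices for the size-|X| screen (the leaves
themselves form an antichain of size |X|) but over NON-LEAF vertices for the
antichain-to-leaf property, matching the two definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, List, Optional, Set, Tuple

import networkx as nx

from .errors import InvalidNetworkError
from .network_core import PhyloNetwork, require_valid

HOLDS = "holds"
FAILS = "fails"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Antichain:
    """A set of vertices with no directed path between any two members."""

    members: FrozenSet[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClassReport:
    """Bundle of structural predicates with a quick verdict hint."""

    tree_child: bool
    tree_sibling: bool
    reticulation_visible: bool
    prop3_i: bool  # every reticulation has two out-degree-2 parents
    prop3_ii: bool  # some reticulation has two out-degree-1 parents
    max_antichain_size: int
    leaf_count: int
    verdict_hint: str  # tree_based | not_tree_based | inconclusive


def _closure(net: PhyloNetwork) -> nx.DiGraph:
    return nx.transitive_closure_dag(nx.DiGraph(net.simple_digraph()))


def is_antichain(net: PhyloNetwork, members: Set[str]) -> bool:
    closure = _closure(net)
    return not any(
        closure.has_edge(u, v) or closure.has_edge(v, u)
        for u, v in combinations(members, 2)
    )


def maximum_antichain(net: PhyloNetwork) -> Antichain:
    """A maximum-cardinality antichain over all vertices, leaves included.

    Dilworth via a minimum chain cover of the reachability order: a maximum
    matching on the bipartite split of the transitive closure gives the cover
    size, and the Koenig vertex cover recovers the antichain (vertices with
    neither copy covered).
    """
    if not net.is_acyclic():
        raise InvalidNetworkError("maximum_antichain requires an acyclic network")
    closure = _closure(net)
    vertices = sorted(net.vertices())
    bip = nx.Graph()
    top = {("L", v) for v in vertices}
    bip.add_nodes_from(top)
    bip.add_nodes_from(("R", v) for v in vertices)
    for u, v in closure.edges():
        if u != v:
            bip.add_edge(("L", u), ("R", v))
    matching = nx.bipartite.maximum_matching(bip, top_nodes=top)
    cover = nx.bipartite.to_vertex_cover(bip, matching, top_nodes=top)
    members = frozenset(
        v for v in vertices if ("L", v) not in cover and ("R", v) not in cover
    )
    return Antichain(members)


def arc_disjoint_paths_to_leaves(net: PhyloNetwork, antichain: Antichain) -> int:
    """Maximum number of arc-disjoint paths from antichain members to X.

    Unit-capacity maximum flow: each member hangs off a super-source with
    capacity 1 (so each member contributes at most one path), parallel arcs
    contribute their multiplicity, and every leaf drains into a super-sink.
    """
    require_valid(net)
    members = set(antichain.members)
    leaves = set(net.leaves())
    if members & leaves:
        raise ValueError("antichain must consist of non-leaf vertices")
    if not is_antichain(net, members):
        raise ValueError("vertex set is not an antichain")
    if not members:
        return 0
    flow_net = nx.DiGraph()
    for u, v, data in net.simple_digraph().edges(data=True):
        flow_net.add_edge(u, v, capacity=data["multiplicity"])
    for member in members:
        flow_net.add_edge("__source__", member, capacity=1)
    for leaf in leaves:
        flow_net.add_edge(leaf, "__sink__", capacity=1)
    value, _ = nx.maximum_flow(flow_net, "__source__", "__sink__")
    return int(value)


def maximal_antichains(net: PhyloNetwork, cap: int = 100_000):
    """Yield maximal antichains of non-leaf vertices (up to ``cap`` of them).

    Maximal antichains are the maximal cliques of the incomparability graph
    of the reachability order restricted to non-leaf vertices.
    """
    closure = _closure(net)
    non_leaves = [v for v in net.vertices() if net.out_degree(v) > 0]
    incomparable = nx.Graph()
    incomparable.add_nodes_from(non_leaves)
    for u, v in combinations(non_leaves, 2):
        if not closure.has_edge(u, v) and not closure.has_edge(v, u):
            incomparable.add_edge(u, v)
    for count, clique in enumerate(nx.find_cliques(incomparable)):
        if count >= cap:
            return
        yield Antichain(frozenset(clique))


def antichain_to_leaf_property(net: PhyloNetwork, cap: int = 100_000) -> str:
    """holds / fails / unknown (the latter if enumeration exceeds ``cap``).

    Checking maximal antichains suffices: any antichain extends to a maximal
    one, and arc-disjoint paths for a superset restrict to the subset.
    """
    require_valid(net)
    count = 0
    for antichain in maximal_antichains(net, cap=cap + 1):
        count += 1
        if count > cap:
            return UNKNOWN
        if arc_disjoint_paths_to_leaves(net, antichain) < len(antichain):
            return FAILS
    return HOLDS


# -- class predicates ------------------------------------------------------


def is_tree_child(net: PhyloNetwork) -> bool:
    """Every non-leaf vertex is the parent of some vertex of in-degree 1."""
    return all(
        any(net.in_degree(c) == 1 for c in net.children(v))
        for v in net.vertices()
        if net.out_degree(v) > 0
    )


def is_tree_sibling(net: PhyloNetwork) -> bool:
    """Every reticulation has a sibling of in-degree 1 via a shared parent.

    A reticulation reached by two parallel arcs has no in-degree-1 sibling
    through that parent (its only co-child there is itself).
    """
    for v in net.reticulations():
        if not any(
            net.in_degree(sib) == 1
            for p in net.parents(v)
            for sib in net.children(p)
            if sib != v
        ):
            return False
    return True


def is_reticulation_visible(net: PhyloNetwork) -> bool:
    """Each reticulation lies on every root-to-x path for some leaf x."""
    root = net.root
    leaves = net.leaves()
    for v in net.reticulations():
        pruned = nx.MultiDiGraph(net.graph)
        pruned.remove_node(v)
        reachable = {root} | nx.descendants(pruned, root)
        if all(leaf in reachable for leaf in leaves):
            return False
    return True


def classify_network(net: PhyloNetwork) -> ClassReport:
    """Evaluate every structural predicate literally from its definition."""
    require_valid(net)
    reticulations = net.reticulations()
    parent_outdegrees = [
        [net.out_degree(a.source) for a in net.in_arcs(v)] for v in reticulations
    ]
    prop3_i = all(degs == [2, 2] for degs in parent_outdegrees)
    prop3_ii = any(degs == [1, 1] for degs in parent_outdegrees)
    tree_child = is_tree_child(net)
    tree_sibling = is_tree_sibling(net)
    visible = is_reticulation_visible(net)
    max_antichain = len(maximum_antichain(net))
    leaf_count = len(net.leaves())
    if prop3_i or tree_child or tree_sibling or visible:
        verdict = "tree_based"
    elif prop3_ii or max_antichain > leaf_count:
        verdict = "not_tree_based"
    else:
        verdict = "inconclusive"
    return ClassReport(
        tree_child=tree_child,
        tree_sibling=tree_sibling,
        reticulation_visible=visible,
        prop3_i=prop3_i,
        prop3_ii=prop3_ii,
        max_antichain_size=max_antichain,
        leaf_count=leaf_count,
        verdict_hint=verdict,
    )
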