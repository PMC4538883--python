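"""Deciding tree-basedness and enumerating support and base trees.

A network N = (V, A) is *tree-based* when it can be obtained from a rooted
binary tree T by subdividing tree arcs and adding *linking arcs* between the
subdivision points.  The characterization implemented here: N is tree-based
iff A has an *admissible* subset S, i.e. one that contains every arc of

    S1 = { a : source(a) has out-degree 1 or target(a) has in-degree 1 }

and satisfies, for every vertex v,

    (C1) if v has in-degree 2, exactly one in-arc of v is in S;
    (C2) if v has out-degree 2, at least one out-arc of v is in S.

Admissible subsets biject with support trees (the subdivided copies of base
trees inside N), so recognition reduces to 2-SAT: one boolean per arc
("in S"), unit clauses for S1, an exactly-one pair per reticulation and an
at-least-one clause per bifurcation.  Two decision routes are provided — the
label-propagation procedure (rules (C1)'/(C2)' below) and an implication-graph
2-SAT solver — plus exhaustive enumeration of all admissible subsets by
branching on the in-arc pairs left open after propagation.

Being *based on* T is strictly stronger than *displaying* T (deleting arcs
and vertices, then suppressing), so the module also enumerates displayed
trees for comparison.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx

from .network_core import (
    PhyloNetwork,
    PhyloTree,
    _suppress_unary,
    require_valid,
    s1_arcs,
    same_network,
)

UNKNOWN = "unknown"

TRUE = "t"
FALSE = "f"


@dataclass
class ArcLabeling:
    """Partial map arc id -> {t, f}; ``None`` marks an unassigned arc."""

    labels: Dict[str, Optional[str]]

    @classmethod
    def empty(cls, net: PhyloNetwork) -> "ArcLabeling":
        return cls({aid: None for aid in net.arc_ids()})

    def copy(self) -> "ArcLabeling":
        return ArcLabeling(dict(self.labels))

    def assigned(self) -> List[str]:
        return sorted(a for a, v in self.labels.items() if v is not None)

    def unassigned(self) -> List[str]:
        return sorted(a for a, v in self.labels.items() if v is None)

    def true_arcs(self) -> Set[str]:
        return {a for a, v in self.labels.items() if v == TRUE}

    def __getitem__(self, arc_id: str) -> Optional[str]:
        return self.labels[arc_id]


@dataclass(frozen=True)
class Conflict:
    """An arc was about to receive a label different from its existing one."""

    arc: str
    existing: str
    attempted: str
    rule: str  # C1a, C1b or C2
    vertex: str  # the vertex whose constraint fired


@dataclass(frozen=True)
class SupportTree:
    """An admissible arc subset S together with its bookkeeping.

    ``S`` spans all of V as a rooted tree whose leaves are exactly the
    network's leaves; ``linking_arcs`` (= A - S) form an independent arc set
    and ``attachment_points`` are the vertices they touch.
    """

    S: FrozenSet[str]
    linking_arcs: FrozenSet[str]
    attachment_points: FrozenSet[str]

    @classmethod
    def from_arcs(cls, net: PhyloNetwork, S: Iterable[str]) -> "SupportTree":
        S = frozenset(S)
        linking = frozenset(net.arc_ids()) - S
        points = set()
        for aid in linking:
            arc = net.arc(aid)
            points.add(arc.source)
            points.add(arc.target)
        return cls(S, linking, frozenset(points))


BaseTree = PhyloTree


class TruncatableList(list):
    """A list with a flag recording whether enumeration hit its limit."""

    truncated: bool = False


@dataclass(frozen=True)
class TwoSatInstance:
    """CNF with 1- and 2-literal clauses; a literal is (arc id, polarity)."""

    variables: Tuple[str, ...]
    clauses: Tuple[Tuple[Tuple[str, bool], ...], ...]


# -- admissibility (the defining constraints, checked directly) ------------


def admissibility_violations(net: PhyloNetwork, S: Iterable[str]) -> List[str]:
    """Why S fails to be admissible; empty list means admissible."""
    S = set(S)
    problems = []
    missing = s1_arcs(net) - S
    if missing:
        problems.append(f"S1 arcs missing from S: {sorted(missing)}")
    for v in net.vertices():
        if net.in_degree(v) == 2:
            chosen = [a.id for a in net.in_arcs(v) if a.id in S]
            if len(chosen) != 1:
                problems.append(f"C1 violated at {v}: {len(chosen)} in-arcs in S")
        if net.out_degree(v) == 2:
            if not any(a.id in S for a in net.out_arcs(v)):
                problems.append(f"C2 violated at {v}: no out-arc in S")
    return problems


def is_admissible(net: PhyloNetwork, S: Iterable[str]) -> bool:
    return not admissibility_violations(net, S)


def support_tree_violations(net: PhyloNetwork, st: SupportTree) -> List[str]:
    """Check the structural invariants every support tree must satisfy."""
    problems = admissibility_violations(net, st.S)
    # (V, S) is a rooted spanning tree with root rho and leaves in X.
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(net.graph.nodes)
    for aid in st.S:
        arc = net.arc(aid)
        sub.add_edge(arc.source, arc.target, key=aid)
    root = net.root
    if not nx.is_directed_acyclic_graph(sub):
        problems.append("(V,S) is not acyclic")
    for v in sub.nodes:
        indeg = sub.in_degree(v)
        if v == root:
            if indeg != 0:
                problems.append(f"root {v} has in-degree {indeg} in S")
        elif indeg != 1:
            problems.append(f"{v} has in-degree {indeg} in S (not a spanning tree)")
    leaves = set(net.leaves())
    for v in sub.nodes:
        if sub.out_degree(v) == 0 and v not in leaves:
            problems.append(f"spanning-tree leaf {v} is not a network leaf")
    # linking arcs form an independent set: no shared endpoints.
    seen: Dict[str, str] = {}
    for aid in sorted(st.linking_arcs):
        arc = net.arc(aid)
        for endpoint in (arc.source, arc.target):
            if endpoint in seen:
                problems.append(
                    f"linking arcs {seen[endpoint]} and {aid} share vertex {endpoint}"
                )
            seen[endpoint] = aid
    return problems


# -- label propagation (rules (C1)' and (C2)') -----------------------------


def initial_labeling(net: PhyloNetwork) -> ArcLabeling:
    """Label every arc of S1 with t; all other arcs start unassigned."""
    forced = s1_arcs(net)
    return ArcLabeling(
        {aid: (TRUE if aid in forced else None) for aid in net.arc_ids()}
    )


def _implications(net: PhyloNetwork, arc_id: str, value: str):
    """Labels implied by ``arc_id = value`` under (C1)' and (C2)'."""
    arc = net.arc(arc_id)
    if net.in_degree(arc.target) == 2:
        sibling = [a.id for a in net.in_arcs(arc.target) if a.id != arc_id]
        if len(sibling) == 1:  # parallel arcs still give two distinct ids
            if value == TRUE:
                yield sibling[0], FALSE, "C1a", arc.target
            else:
                yield sibling[0], TRUE, "C1b", arc.target
    if value == FALSE and net.out_degree(arc.source) == 2:
        sibling = [a.id for a in net.out_arcs(arc.source) if a.id != arc_id]
        if len(sibling) == 1:
            yield sibling[0], TRUE, "C2", arc.source


def propagate_labels(
    net: PhyloNetwork,
    labeling: ArcLabeling,
    rng_seed: Optional[int] = None,
) -> Union[ArcLabeling, Conflict]:
    """Close ``labeling`` under (C1)' and (C2)', or return the first Conflict.

    The fixpoint is independent of the application order (each rule is a
    sound implication of the admissibility constraints); the default FIFO
    worklist is seeded in ascending arc-id order so conflict witnesses are
    deterministic.  ``rng_seed`` shuffles the worklist seed order, which is
    used by the confluence tests.
    """
    state = labeling.copy()
    queue = state.assigned()
    if rng_seed is not None:
        random.Random(rng_seed).shuffle(queue)
    while queue:
        arc_id = queue.pop(0)
        value = state.labels[arc_id]
        for other, implied, rule, vertex in _implications(net, arc_id, value):
            existing = state.labels[other]
            if existing is None:
                state.labels[other] = implied
                queue.append(other)
            elif existing != implied:
                return Conflict(other, existing, implied, rule, vertex)
    return state


# -- 2-SAT ------------------------------------------------------------------


def build_2sat(net: PhyloNetwork) -> TwoSatInstance:
    """Encode admissibility: units for S1, exactly-one per reticulation,
    at-least-one per bifurcation."""
    require_valid(net)
    clauses: List[Tuple[Tuple[str, bool], ...]] = []
    for aid in sorted(s1_arcs(net)):
        clauses.append(((aid, True),))
    for v in net.vertices():
        if net.in_degree(v) == 2:
            a, b = (arc.id for arc in net.in_arcs(v))
            clauses.append(((a, True), (b, True)))
            clauses.append(((a, False), (b, False)))
        if net.out_degree(v) == 2:
            c, d = (arc.id for arc in net.out_arcs(v))
            clauses.append(((c, True), (d, True)))
    return TwoSatInstance(tuple(net.arc_ids()), tuple(clauses))


def solve_2sat(instance: TwoSatInstance) -> Optional[Dict[str, bool]]:
    """Satisfying assignment via the implication graph and its SCCs.

    Returns ``None`` when unsatisfiable (some variable shares a strongly
    connected component with its own negation).
    """
    implications = nx.DiGraph()
    for var in instance.variables:
        implications.add_node((var, True))
        implications.add_node((var, False))
    for clause in instance.clauses:
        if len(clause) not in (1, 2) or any(
            not (isinstance(v, str) and isinstance(p, bool)) for v, p in clause
        ):
            raise ValueError(f"malformed clause {clause!r}")
        if len(clause) == 1:
            ((var, pol),) = clause
            implications.add_edge((var, not pol), (var, pol))
        else:
            (v1, p1), (v2, p2) = clause
            implications.add_edge((v1, not p1), (v2, p2))
            implications.add_edge((v2, not p2), (v1, p1))
    component_of: Dict[Tuple[str, bool], int] = {}
    components = list(nx.strongly_connected_components(implications))
    for idx, comp in enumerate(components):
        for node in comp:
            component_of[node] = idx
    condensation = nx.condensation(implications, components)
    order = {c: i for i, c in enumerate(nx.topological_sort(condensation))}
    assignment: Dict[str, bool] = {}
    for var in instance.variables:
        pos, neg = component_of[(var, True)], component_of[(var, False)]
        if pos == neg:
            return None
        # A literal is true when its SCC comes later in topological order.
        assignment[var] = order[pos] > order[neg]
    return assignment


# -- the decision procedure -------------------------------------------------


def is_tree_based(net: PhyloNetwork, method: str = "2sat") -> bool:
    """Does an admissible arc subset (equivalently, a support tree) exist?

    ``method="2sat"`` solves the full instance; ``method="propagate"`` runs
    the label-propagation procedure first and falls back to 2-SAT on the
    residual instance when arcs remain open.  Both agree on every input.
    """
    require_valid(net)
    if method == "2sat":
        return solve_2sat(build_2sat(net)) is not None
    if method == "propagate":
        outcome = propagate_labels(net, initial_labeling(net))
        if isinstance(outcome, Conflict):
            return False
        if not outcome.unassigned():
            return True
        base = build_2sat(net)
        units = tuple(
            ((aid, value == TRUE),)
            for aid, value in sorted(outcome.labels.items())
            if value is not None
        )
        residual = TwoSatInstance(base.variables, base.clauses + units)
        return solve_2sat(residual) is not None
    raise ValueError(f"unknown method {method!r}")


def enumerate_support_trees(net: PhyloNetwork, limit: int = 1024) -> TruncatableList:
    """All admissible subsets, by branching on open reticulation in-arc pairs.

    Branches on the unassigned pair of the lowest-id reticulation, trying t
    before f on the pair's lower-id arc, so the output order is reproducible.
    Every returned :class:`SupportTree` is re-checked against its full
    invariant block.  Truncation at ``limit`` sets ``result.truncated``.
    """
    require_valid(net)
    if limit < 1:
        raise ValueError("limit must be positive")
    result = TruncatableList()
    start = propagate_labels(net, initial_labeling(net))
    if isinstance(start, Conflict):
        return result

    def open_pair(state: ArcLabeling) -> Optional[str]:
        for v in net.reticulations():
            pair = net.in_arcs(v)
            if any(state.labels[a.id] is None for a in pair):
                return pair[0].id
        return None

    def branch(state: ArcLabeling) -> bool:
        """Depth-first; returns False once the limit is exceeded."""
        arc_id = open_pair(state)
        if arc_id is None:
            if len(result) >= limit:
                result.truncated = True
                return False
            st = SupportTree.from_arcs(net, state.true_arcs())
            problems = support_tree_violations(net, st)
            if problems:  # pragma: no cover - internal consistency guard
                raise AssertionError(f"enumerated non-admissible set: {problems}")
            result.append(st)
            return True
        for value in (TRUE, FALSE):
            attempt = state.copy()
            attempt.labels[arc_id] = value
            outcome = propagate_labels(net, attempt)
            if isinstance(outcome, Conflict):
                continue
            if not branch(outcome):
                return False
        return True

    branch(start)
    return result


# -- base trees and displayed trees ----------------------------------------


def base_tree(net: PhyloNetwork, support: Union[SupportTree, Iterable[str]]) -> BaseTree:
    """Drop the linking arcs A - S and suppress every degree-(1,1) vertex."""
    S = support.S if isinstance(support, SupportTree) else frozenset(support)
    problems = admissibility_violations(net, S)
    if problems:
        raise ValueError("arc set is not admissible: " + "; ".join(problems))
    tree = PhyloTree()
    for v in net.vertices():
        tree.add_vertex(v, net.label(v))
    for aid in sorted(S):
        arc = net.arc(aid)
        tree.add_arc(arc.source, arc.target, arc_id=aid)
    _suppress_unary(tree)
    return tree


def _dedup_trees(trees: Sequence[BaseTree]) -> List[BaseTree]:
    distinct: List[BaseTree] = []
    for tree in trees:
        if not any(same_network(tree, seen) for seen in distinct):
            distinct.append(tree)
    return distinct


def base_trees(net: PhyloNetwork, limit: int = 1024) -> TruncatableList:
    """Deduplicated base trees over all support trees (up to ``limit``)."""
    supports = enumerate_support_trees(net, limit)
    result = TruncatableList(_dedup_trees([base_tree(net, st) for st in supports]))
    result.truncated = supports.truncated
    return result


def is_based_on(
    net: PhyloNetwork, tree: PhyloNetwork, limit: int = 1024
) -> Union[bool, str]:
    """Brute force over enumerated support trees; three-valued.

    Returns ``"unknown"`` when enumeration was truncated before finding the
    tree — exact support-tree counting is #P-hard, so silent truncation would
    be unsound.
    """
    require_valid(tree)
    if set(tree.leaf_labels()) != set(net.leaf_labels()):
        raise ValueError("tree and network have different leaf sets")
    candidates = base_trees(net, limit)
    if any(same_network(tree, cand) for cand in candidates):
        return True
    return UNKNOWN if candidates.truncated else False


def displayed_trees(net: PhyloNetwork, limit: int = 1024) -> TruncatableList:
    """Trees obtained by keeping one in-arc per reticulation, then pruning.

    For each of the <= 2^k switchings, the discarded reticulation in-arcs are
    deleted, vertices with no remaining path to a leaf are removed, and
    degree-(1,1) vertices are suppressed.  Choices that fail to leave a
    binary tree on all of X are discarded; the survivors are deduplicated.
    """
    require_valid(net)
    if limit < 1:
        raise ValueError("limit must be positive")
    reticulations = net.reticulations()
    labels = set(net.leaf_labels())
    leaf_vertices = net.leaves()
    found: List[BaseTree] = []
    result = TruncatableList()

    def switchings(idx: int, removed: List[str]):
        if idx == len(reticulations):
            yield list(removed)
            return
        for drop in net.in_arcs(reticulations[idx]):
            removed.append(drop.id)
            yield from switchings(idx + 1, removed)
            removed.pop()

    count = 0
    for removed in switchings(0, []):
        count += 1
        if count > limit:
            result.truncated = True
            break
        pruned = net.copy()
        for aid in removed:
            pruned.remove_arc(aid)
        g = pruned.graph
        useful = set(leaf_vertices) | set().union(
            *(nx.ancestors(g, leaf) for leaf in leaf_vertices)
        )
        for v in sorted(set(g.nodes) - useful):
            pruned.remove_vertex(v)
        _suppress_unary(pruned)
        candidate = PhyloTree()
        candidate._g = pruned._g
        candidate._arc_index = pruned._arc_index
        report_ok = (
            candidate.reticulation_count == 0
            and set(candidate.leaf_labels()) == labels
            and not [
                v
                for v in candidate.vertices()
                if candidate.out_degree(v) > 2
            ]
        )
        if report_ok and not any(same_network(candidate, t) for t in found):
            found.append(candidate)
    result.extend(found)
    return result
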