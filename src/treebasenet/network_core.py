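"""Data model, validation and I/O for rooted binary phylogenetic networks.

A binary phylogenetic network over a taxon set ``X`` is a rooted directed
acyclic graph in which the leaves (out-degree 0, in-degree 1) are bijectively
labeled by ``X``, a unique root has in-degree 0 and out-degree 1 or 2, and
every other vertex is either a *reticulation* (in-degree 2, out-degree 1) or a
*tree vertex* (in-degree 1, out-degree 2).  Parallel arcs are legal, so arcs
carry their own identity and the graph is stored as a multidigraph.

Three serializations are supported:

``edgelist-json``
    The canonical on-disk format (schema ``treebase-net-v1``): a JSON object
    with ``vertices`` (``{"id": ..., "label": ...}``; label present iff leaf)
    and ``arcs`` (``{"id": ..., "source": ..., "target": ...}``).  This is the
    only format that can express every legal network unambiguously, because
    parallel arcs and out-degree-1 roots are awkward in Newick dialects.

``enewick``
    Extended Newick with the ``#H`` hybrid-node convention: every occurrence
    of the same ``#Hk`` tag denotes the same vertex; listing the same hybrid
    twice under one parent produces parallel arcs.

``newick``
    Plain Newick, for networks with zero reticulations (rooted binary trees).

Branch lengths are parsed when present and ignored by every algorithm.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import FormatError, InvalidNetworkError, ParseError

JSON_FORMAT_TAG = "treebase-net-v1"


@dataclass(frozen=True)
class Vertex:
    """A network vertex; ``label`` is the taxon name and is present iff leaf."""

    id: str
    label: Optional[str] = None


@dataclass(frozen=True)
class Arc:
    """A directed arc.  Identity is by ``id``, never by endpoint pair."""

    id: str
    source: str
    target: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_network`; violations are data, not errors."""

    violations: List[Tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def add(self, code: str, ref: str, message: str) -> None:
        self.violations.append((code, ref, message))

    def codes(self) -> Set[str]:
        return {code for code, _, _ in self.violations}


class PhyloNetwork:
    """Rooted binary phylogenetic network (parallel arcs allowed).

    Thin wrapper around a :class:`networkx.MultiDiGraph`; vertex ids and arc
    ids are strings, and arc ids are the multigraph edge keys.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._arc_index: Dict[str, Tuple[str, str]] = {}
        self._auto_arc = 0

    # -- construction -----------------------------------------------------

    def add_vertex(self, vertex_id: str, label: Optional[str] = None) -> str:
        vertex_id = str(vertex_id)
        if vertex_id in self._g:
            existing = self._g.nodes[vertex_id].get("label")
            if label is not None and existing is not None and existing != label:
                raise ValueError(f"vertex {vertex_id!r} relabeled {existing!r} -> {label!r}")
            if label is not None:
                self._g.nodes[vertex_id]["label"] = label
            return vertex_id
        self._g.add_node(vertex_id, label=label)
        return vertex_id

    def add_arc(
        self,
        source: str,
        target: str,
        arc_id: Optional[str] = None,
        length: Optional[float] = None,
    ) -> str:
        source, target = str(source), str(target)
        if arc_id is None:
            while True:
                arc_id = f"e{self._auto_arc:04d}"
                self._auto_arc += 1
                if arc_id not in self._arc_index:
                    break
        arc_id = str(arc_id)
        if arc_id in self._arc_index:
            raise ValueError(f"duplicate arc id {arc_id!r}")
        for v in (source, target):
            if v not in self._g:
                self.add_vertex(v)
        self._g.add_edge(source, target, key=arc_id, length=length)
        self._arc_index[arc_id] = (source, target)
        return arc_id

    def remove_arc(self, arc_id: str) -> None:
        source, target = self._arc_index.pop(arc_id)
        self._g.remove_edge(source, target, key=arc_id)

    def remove_vertex(self, vertex_id: str) -> None:
        for arc in list(self.in_arcs(vertex_id)) + list(self.out_arcs(vertex_id)):
            if arc.id in self._arc_index:
                self.remove_arc(arc.id)
        self._g.remove_node(vertex_id)

    def subdivide_arc(self, arc_id: str, new_vertex_id: str) -> Tuple[str, str]:
        """Replace arc (u,v) by (u,w),(w,v); returns the two new arc ids."""
        source, target = self._arc_index[arc_id]
        self.remove_arc(arc_id)
        self.add_vertex(new_vertex_id)
        upper = self.add_arc(source, new_vertex_id)
        lower = self.add_arc(new_vertex_id, target)
        return upper, lower

    def copy(self) -> "PhyloNetwork":
        clone = type(self)()
        clone._g = self._g.copy()
        clone._arc_index = dict(self._arc_index)
        clone._auto_arc = self._auto_arc
        return clone

    # -- accessors --------------------------------------------------------

    def vertices(self) -> List[str]:
        return sorted(self._g.nodes)

    def label(self, vertex_id: str) -> Optional[str]:
        return self._g.nodes[vertex_id].get("label")

    def vertex(self, vertex_id: str) -> Vertex:
        return Vertex(vertex_id, self.label(vertex_id))

    def arcs(self) -> List[Arc]:
        return [Arc(aid, st[0], st[1]) for aid, st in sorted(self._arc_index.items())]

    def arc(self, arc_id: str) -> Arc:
        source, target = self._arc_index[arc_id]
        return Arc(arc_id, source, target)

    def arc_ids(self) -> List[str]:
        return sorted(self._arc_index)

    def has_arc(self, arc_id: str) -> bool:
        return arc_id in self._arc_index

    def in_degree(self, vertex_id: str) -> int:
        return self._g.in_degree(vertex_id)

    def out_degree(self, vertex_id: str) -> int:
        return self._g.out_degree(vertex_id)

    def in_arcs(self, vertex_id: str) -> List[Arc]:
        return sorted(
            (Arc(key, u, v) for u, v, key in self._g.in_edges(vertex_id, keys=True)),
            key=lambda a: a.id,
        )

    def out_arcs(self, vertex_id: str) -> List[Arc]:
        return sorted(
            (Arc(key, u, v) for u, v, key in self._g.out_edges(vertex_id, keys=True)),
            key=lambda a: a.id,
        )

    def parents(self, vertex_id: str) -> List[str]:
        return [a.source for a in self.in_arcs(vertex_id)]

    def children(self, vertex_id: str) -> List[str]:
        return [a.target for a in self.out_arcs(vertex_id)]

    @property
    def root(self) -> str:
        roots = [v for v in self._g.nodes if self._g.in_degree(v) == 0]
        if len(roots) != 1:
            raise InvalidNetworkError(f"expected a unique root, found {sorted(roots)}")
        return roots[0]

    def leaves(self) -> List[str]:
        return sorted(v for v in self._g.nodes if self._g.out_degree(v) == 0)

    def leaf_labels(self) -> List[str]:
        labels = [self.label(v) for v in self.leaves()]
        return sorted(lab for lab in labels if lab is not None)

    def leaf_by_label(self, label: str) -> str:
        for v in self.leaves():
            if self.label(v) == label:
                return v
        raise KeyError(label)

    def reticulations(self) -> List[str]:
        return sorted(v for v in self._g.nodes if self._g.in_degree(v) == 2)

    @property
    def reticulation_count(self) -> int:
        return len(self.reticulations())

    @property
    def graph(self) -> nx.MultiDiGraph:
        """The underlying multidigraph (treat as read-only)."""
        return self._g

    def simple_digraph(self) -> nx.DiGraph:
        """Collapse parallel arcs; edge attr ``multiplicity`` keeps the count."""
        g = nx.DiGraph()
        g.add_nodes_from(self._g.nodes)
        for u, v in self._g.edges():
            if g.has_edge(u, v):
                g[u][v]["multiplicity"] += 1
            else:
                g.add_edge(u, v, multiplicity=1)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._g)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<{type(self).__name__} |V|={self._g.number_of_nodes()} "
            f"|A|={self._g.number_of_edges()} leaves={self.leaf_labels()}>"
        )


class PhyloTree(PhyloNetwork):
    """A binary phylogenetic network with zero reticulations."""


def build_network(
    arcs: Sequence[Tuple[str, str]],
    labels: Optional[Dict[str, str]] = None,
    cls=PhyloNetwork,
) -> PhyloNetwork:
    """Build a network from (source, target) pairs.

    Out-degree-0 vertices are labeled by their own id unless ``labels``
    overrides this.  Arc ids are assigned in listing order, so "lowest arc id"
    choices made by the algorithms follow the listing order of ``arcs``.
    """
    net = cls()
    for source, target in arcs:
        net.add_arc(source, target)
    targets = {t for _, t in arcs}
    sources = {s for s, _ in arcs}
    labels = labels or {}
    for v in sorted(targets - sources):
        net.add_vertex(v, labels.get(v, v))
    for v, lab in labels.items():
        net.add_vertex(v, lab)
    return net


# -- validation -----------------------------------------------------------


def validate_network(net: PhyloNetwork) -> ValidationReport:
    """Check the binary phylogenetic network axioms, reporting every violation."""
    report = ValidationReport()
    g = net.graph
    if g.number_of_nodes() == 0:
        report.add("empty", "-", "network has no vertices")
        return report

    roots = sorted(v for v in g.nodes if g.in_degree(v) == 0)
    if len(roots) == 0:
        report.add("no_root", "-", "no vertex of in-degree 0")
    elif len(roots) > 1:
        report.add("multiple_roots", ",".join(roots), "more than one vertex of in-degree 0")
    else:
        root = roots[0]
        if g.out_degree(root) not in (1, 2):
            report.add("root_degree", root, f"root out-degree {g.out_degree(root)} not in (1, 2)")

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        report.add("cycle", "->".join(str(u) for u, _, _ in cycle), "directed cycle present")

    seen_labels: Counter = Counter()
    for v in sorted(g.nodes):
        din, dout = g.in_degree(v), g.out_degree(v)
        label = g.nodes[v].get("label")
        if dout == 0:
            if din != 1:
                report.add("leaf_degree", v, f"leaf has in-degree {din}, expected 1")
            if label is None:
                report.add("unlabeled_leaf", v, "out-degree-0 vertex has no taxon label")
            else:
                seen_labels[label] += 1
        else:
            if label is not None:
                report.add("labeled_internal", v, f"non-leaf vertex carries label {label!r}")
            if din == 0:
                continue  # root, handled above
            if (din, dout) not in ((1, 2), (2, 1)):
                report.add("degree", v, f"vertex degree ({din},{dout}) not (1,2) or (2,1)")
    for label, count in sorted(seen_labels.items()):
        if count > 1:
            report.add("duplicate_label", label, f"taxon label used by {count} leaves")
    return report


def require_valid(net: PhyloNetwork) -> None:
    report = validate_network(net)
    if not report.is_valid:
        raise InvalidNetworkError(
            "not a valid binary phylogenetic network: "
            + "; ".join(f"{c}@{r}" for c, r, _ in report.violations),
            report=report,
        )


# -- S1 and restriction ----------------------------------------------------


def s1_arcs(net: PhyloNetwork) -> Set[str]:
    """Arcs whose source has out-degree 1 or whose target has in-degree 1.

    These are forced into every support tree; the arcs left out are exactly
    the in-arc pairs of reticulations whose sources have out-degree 2.
    """
    require_valid(net)
    return {
        a.id
        for a in net.arcs()
        if net.out_degree(a.source) == 1 or net.in_degree(a.target) == 1
    }


def _suppress_unary(net: PhyloNetwork) -> None:
    """Suppress every vertex of in-degree 1 and out-degree 1, in place.

    The merged arc inherits the id of the incoming arc, which keeps the
    outcome deterministic; suppression may create parallel arcs.
    """
    while True:
        unary = [
            v
            for v in net.vertices()
            if net.in_degree(v) == 1 and net.out_degree(v) == 1
        ]
        if not unary:
            return
        for v in unary:
            if net.in_degree(v) != 1 or net.out_degree(v) != 1:
                continue
            (inc,) = net.in_arcs(v)
            (out,) = net.out_arcs(v)
            net.remove_arc(inc.id)
            net.remove_arc(out.id)
            net.remove_vertex(v)
            net.add_arc(inc.source, out.target, arc_id=inc.id)


def restrict_to_leaves(net: PhyloNetwork, labels: Iterable[str]) -> PhyloNetwork:
    """Restriction N|X': keep vertices on a path to a leaf in X', then suppress.

    Deletes every vertex and arc that does not lie on a directed path to a
    leaf labeled in ``labels``, then suppresses all resulting vertices of
    in-degree and out-degree 1.
    """
    wanted = set(labels)
    if not wanted:
        raise ValueError("restriction to an empty leaf set")
    have = set(net.leaf_labels())
    if not wanted <= have:
        raise ValueError(f"labels {sorted(wanted - have)} are not leaves of the network")
    leaf_vertices = {net.leaf_by_label(lab) for lab in wanted}
    keep = set(leaf_vertices)
    for v in leaf_vertices:
        keep |= nx.ancestors(net.graph, v)
    restricted = type(net)()
    for v in sorted(keep):
        restricted.add_vertex(v, net.label(v) if v in leaf_vertices else None)
    for arc in net.arcs():
        if arc.source in keep and arc.target in keep:
            restricted.add_arc(arc.source, arc.target, arc_id=arc.id)
    _suppress_unary(restricted)
    return restricted


# -- isomorphism ----------------------------------------------------------


def cluster_set(tree: PhyloNetwork) -> FrozenSet[frozenset]:
    """Set of descendant-leaf-label sets over all vertices (trees only)."""
    memo: Dict[str, frozenset] = {}

    def descend(v: str) -> frozenset:
        if v in memo:
            return memo[v]
        if tree.out_degree(v) == 0:
            result = frozenset([tree.label(v)])
        else:
            result = frozenset().union(*(descend(c) for c in tree.children(v)))
        memo[v] = result
        return result

    return frozenset(descend(v) for v in tree.vertices())


def same_network(net1: PhyloNetwork, net2: PhyloNetwork) -> bool:
    """Leaf-label-preserving isomorphism (root maps to root automatically).

    For reticulation-free inputs this reduces to equality of the sets of
    leaf clusters, which deliberately identifies trees that differ only by a
    root vertex of out-degree 1 (the root edge carries no phylogenetic
    signal); the general case runs VF2 on the multidigraphs with leaf labels
    as the node invariant.
    """
    require_valid(net1)
    require_valid(net2)
    if set(net1.leaf_labels()) != set(net2.leaf_labels()):
        return False
    if net1.reticulation_count == 0 and net2.reticulation_count == 0:
        return cluster_set(net1) == cluster_set(net2)
    if net1.reticulation_count != net2.reticulation_count:
        return False
    matcher = nx.algorithms.isomorphism.MultiDiGraphMatcher(
        net1.graph,
        net2.graph,
        node_match=lambda a, b: a.get("label") == b.get("label"),
    )
    return matcher.is_isomorphic()


# -- parsing ---------------------------------------------------------------

_HYBRID_RE = re.compile(r"#([A-Za-z]*)(\d+)$")
_TOKEN_RE = re.compile(r"\s*([(),;]|[^(),;\s]+)")


def _infer_format(text: str) -> str:
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return "edgelist-json"
    if "#" in stripped:
        return "enewick"
    return "newick"


class _NewickParser:
    """Recursive-descent parser for Newick / extended Newick."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> ParseError:
        line = self.text.count("\n", 0, self.pos) + 1
        column = self.pos - (self.text.rfind("\n", 0, self.pos) + 1) + 1
        return ParseError(f"{message} (line {line}, column {column})", line, column)

    def peek(self) -> Optional[str]:
        m = _TOKEN_RE.match(self.text, self.pos)
        return m.group(1) if m else None

    def take(self) -> str:
        m = _TOKEN_RE.match(self.text, self.pos)
        if not m:
            raise self.error("unexpected end of input")
        self.pos = m.end()
        return m.group(1)

    def parse(self) -> dict:
        node = self.subtree()
        tok = self.peek()
        if tok != ";":
            raise self.error(f"expected ';', found {tok!r}")
        self.take()
        return node

    def subtree(self) -> dict:
        node = {"name": None, "hybrid": None, "length": None, "children": []}
        if self.peek() == "(":
            self.take()
            node["children"].append(self.subtree())
            while self.peek() == ",":
                self.take()
                node["children"].append(self.subtree())
            if self.peek() != ")":
                raise self.error(f"expected ')', found {self.peek()!r}")
            self.take()
        tok = self.peek()
        if tok is not None and tok not in "(),;":
            self.take()
            label = tok
            if ":" in label:
                label, _, length = label.partition(":")
                try:
                    node["length"] = float(length)
                except ValueError:
                    raise self.error(f"bad branch length {length!r}")
            m = _HYBRID_RE.search(label)
            if m:
                node["hybrid"] = label[m.start() + 1 :]
                label = label[: m.start()]
            node["name"] = label or None
        return node


def _network_from_newick(text: str) -> PhyloNetwork:
    root_node = _NewickParser(text).parse()
    net = PhyloNetwork()
    hybrid_vertex: Dict[str, str] = {}
    hybrid_counts: Counter = Counter()
    auto = [0]

    def vertex_for(node: dict) -> str:
        tag = node["hybrid"]
        if tag is not None:
            hybrid_counts[tag] += 1
            if tag in hybrid_vertex:
                vid = hybrid_vertex[tag]
                if node["name"]:
                    net.add_vertex(vid)  # merged occurrence; name may repeat
                return vid
            vid = node["name"] or tag
            hybrid_vertex[tag] = net.add_vertex(vid)
            return vid
        if node["name"] and not node["children"]:
            return net.add_vertex(node["name"])
        vid = node["name"] or f"n{auto[0]}"
        auto[0] += 1
        return net.add_vertex(vid)

    def walk(node: dict, parent: Optional[str]) -> None:
        vid = vertex_for(node)
        if parent is not None:
            net.add_arc(parent, vid, length=node["length"])
        for child in node["children"]:
            walk(child, vid)

    walk(root_node, None)
    for tag, count in hybrid_counts.items():
        if count < 2:
            raise ParseError(f"hybrid tag #{tag} appears only once")
    for v in net.leaves():
        label = net.label(v)
        if label is None:
            net.graph.nodes[v]["label"] = v
    return net


def _network_from_json(text: str) -> PhyloNetwork:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"bad JSON: {exc.msg}", exc.lineno, exc.colno)
    if not isinstance(payload, dict) or "arcs" not in payload:
        raise ParseError("edgelist JSON must be an object with an 'arcs' list")
    net = PhyloNetwork()
    for entry in payload.get("vertices", []):
        net.add_vertex(entry["id"], entry.get("label"))
    for entry in payload["arcs"]:
        try:
            net.add_arc(
                entry["source"],
                entry["target"],
                arc_id=entry.get("id"),
                length=entry.get("length"),
            )
        except KeyError as exc:
            raise ParseError(f"arc entry missing field {exc}")
    return net


def parse_network(text: str, fmt: Optional[str] = None) -> PhyloNetwork:
    """Deserialize a network; ``fmt`` in {enewick, edgelist-json, newick}.

    Parsing does not validate the binary-network axioms — use
    :func:`validate_network` — so malformed or cyclic inputs can still be
    loaded and reported on.
    """
    if not text or not text.strip():
        raise ParseError("empty input")
    fmt = fmt or _infer_format(text)
    if fmt == "edgelist-json":
        return _network_from_json(text)
    if fmt in ("enewick", "newick"):
        return _network_from_newick(text)
    raise FormatError(f"unknown format {fmt!r}")


# -- writing ---------------------------------------------------------------


def _network_to_json(net: PhyloNetwork) -> str:
    payload = {
        "format": JSON_FORMAT_TAG,
        "vertices": [
            {"id": v, **({"label": net.label(v)} if net.label(v) is not None else {})}
            for v in net.vertices()
        ],
        "arcs": [
            {"id": a.id, "source": a.source, "target": a.target} for a in net.arcs()
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=False)


def _network_to_newick(net: PhyloNetwork, allow_hybrids: bool) -> str:
    if not net.is_acyclic():
        raise FormatError("cyclic graphs have no Newick form; use edgelist-json")
    reticulations = net.reticulations()
    if reticulations and not allow_hybrids:
        raise FormatError("plain Newick cannot express reticulations; use enewick")
    hybrid_tag = {v: f"H{i + 1}" for i, v in enumerate(reticulations)}
    # The subtree of a reticulation is written below its lowest-id in-arc;
    # other in-arcs produce bare #H references.
    primary_in = {v: net.in_arcs(v)[0].id for v in reticulations}

    def render(v: str, via_arc: Optional[str]) -> Tuple[str, str]:
        tag = hybrid_tag.get(v)
        if tag is not None and via_arc != primary_in[v]:
            return f"#{tag}", f"#{tag}"
        label = net.label(v) or ""
        suffix = f"{label}#{tag}" if tag is not None else label
        if net.out_degree(v) == 0:
            return suffix, label
        parts = [render(a.target, a.id) for a in net.out_arcs(v)]
        parts.sort(key=lambda p: p[1])
        text = "(" + ",".join(p[0] for p in parts) + ")" + suffix
        return text, min(p[1] for p in parts)

    return render(net.root, None)[0] + ";"


def write_network(net: PhyloNetwork, fmt: str = "edgelist-json") -> str:
    """Serialize; round-trips up to isomorphism in every format."""
    if fmt == "edgelist-json":
        return _network_to_json(net)
    if fmt == "enewick":
        return _network_to_newick(net, allow_hybrids=True)
    if fmt == "newick":
        return _network_to_newick(net, allow_hybrids=False)
    raise FormatError(f"unknown format {fmt!r}")
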