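"""Figure fixtures and synthetic network generators.

The fixtures are hand transcriptions of the published figure networks
(stored as documented edgelist-json files under ``treebasenet/fixtures/``);
each ships with caption-derived expected properties that the test suite
asserts.  Vertex names from the captions (u, v, w, x, ...) are preserved as
ids where the text fixes them; all other ids are the transcriber's choice
and affect nothing observable.

The synthetic generators implement the generative definition of tree-based:
``add_linking_arcs`` grows a network from a base tree by subdividing two
support-tree arcs and joining the fresh attachment points with a linking arc
(so its outputs are tree-based by construction), while
``random_binary_network`` allows linking arcs to start or end on earlier
linking arcs as well, producing valid binary networks with no
tree-basedness guarantee — the negative-path exerciser.
"""

from __future__ import annotations

import json
import random
from importlib import resources
from typing import List, Optional

import networkx as nx

from .errors import GenerationError
from .network_core import PhyloNetwork, PhyloTree, parse_network

FIXTURE_NAMES = (
    "fig1",
    "fig2i",
    "fig2ii",
    "fig2iii",
    "fig3",
    "fig4_wheat",
    "fig5",
    "fig6i",
    "fig6ii",
    "fig6iii",
    # extra desk examples used throughout the documentation and tests
    "parallel",
    "double_diamond",
)


def fixture(name: str) -> PhyloNetwork:
    """Load a named figure network (or desk example) from its JSON file."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    text = (
        resources.files("treebasenet").joinpath(f"fixtures/{name}.json").read_text()
    )
    return parse_network(text, "edgelist-json")


def random_base_tree(n: int, seed: int) -> PhyloTree:
    """Rooted binary tree on leaves L1..Ln by sequential random attachment.

    Starts from the cherry (L1, L2) and repeatedly subdivides a uniformly
    chosen arc to hang the next leaf; 2n-1 vertices and 2n-2 arcs.
    """
    if n < 2:
        raise ValueError("a rooted binary tree needs at least 2 leaves")
    rng = random.Random(seed)
    tree = PhyloTree()
    tree.add_vertex("v0")
    tree.add_vertex("L1", "L1")
    tree.add_vertex("L2", "L2")
    tree.add_arc("v0", "L1")
    tree.add_arc("v0", "L2")
    for i in range(3, n + 1):
        arc_id = rng.choice(tree.arc_ids())
        attach = f"v{i - 2}"
        tree.subdivide_arc(arc_id, attach)
        leaf = f"L{i}"
        tree.add_vertex(leaf, leaf)
        tree.add_arc(attach, leaf)
    return tree


def _as_network(tree: PhyloNetwork) -> PhyloNetwork:
    net = PhyloNetwork()
    net._g = tree.graph.copy()
    net._arc_index = {a.id: (a.source, a.target) for a in tree.arcs()}
    net._auto_arc = tree._auto_arc
    return net


def _grow(
    tree: PhyloTree,
    k: int,
    seed: int,
    max_tries: int,
    tree_arcs_only: bool,
) -> PhyloNetwork:
    rng = random.Random(seed)
    net = _as_network(tree)
    tree_arcs = set(net.arc_ids())
    for i in range(k):
        for attempt in range(max_tries):
            pool = sorted(tree_arcs) if tree_arcs_only else net.arc_ids()
            first = rng.choice(pool)
            second = rng.choice(pool)
            candidate = net.copy()
            cand_tree_arcs = set(tree_arcs)
            src_point, tgt_point = f"u{i}", f"w{i}"
            if first == second:
                # Two attachment points on the same arc: the linking arc runs
                # from the upper to the lower one (may create parallel arcs).
                a1, a2 = candidate.subdivide_arc(first, src_point)
                b1, b2 = candidate.subdivide_arc(a2, tgt_point)
                new_halves = {a1, b1, b2}
            else:
                a1, a2 = candidate.subdivide_arc(first, src_point)
                b1, b2 = candidate.subdivide_arc(second, tgt_point)
                new_halves = {a1, a2, b1, b2}
                if nx.has_path(candidate.graph, tgt_point, src_point):
                    continue  # the linking arc would close a directed cycle
            if first in cand_tree_arcs:
                cand_tree_arcs.discard(first)
                cand_tree_arcs.update({a1, a2} if first != second else {a1, b1, b2})
            if second in cand_tree_arcs and first != second:
                cand_tree_arcs.discard(second)
                cand_tree_arcs.update({b1, b2})
            candidate.add_arc(src_point, tgt_point)
            net, tree_arcs = candidate, cand_tree_arcs
            break
        else:
            raise GenerationError(
                f"no acyclic placement for linking arc {i + 1} after {max_tries} tries"
            )
    return net


def add_linking_arcs(
    tree: PhyloTree, k: int, seed: int, max_tries: int = 200
) -> PhyloNetwork:
    """Add k linking arcs between fresh subdivision points of support arcs.

    Only support-tree arcs are ever subdivided (a linking arc may not start
    or end on another linking arc), so the result is tree-based with the
    input tree among its base trees; 2 vertices and 3 arcs are added per
    linking arc.  Raises :class:`GenerationError` if no acyclic placement is
    found within ``max_tries`` — never a silent partial result.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    return _grow(tree, k, seed, max_tries, tree_arcs_only=True)


def random_binary_network(
    n: int, k: int, seed: int, max_tries: int = 200
) -> PhyloNetwork:
    """A valid binary network with n leaves and k reticulations.

    Grown like :func:`add_linking_arcs` but any arc — including earlier
    linking arcs and arcs below reticulations — may be subdivided, so the
    output carries no tree-basedness guarantee.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if k < 0:
        raise ValueError("k must be non-negative")
    tree = random_base_tree(n, seed)
    return _grow(tree, k, seed + 1, max_tries, tree_arcs_only=False)
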